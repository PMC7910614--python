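import numpy as np
import pytest

from radnte._propagate import Propagator
from radnte.dose_decay import DoseDecayFit
from radnte.nte_core import (
    DegenerateDenominatorError,
    ModelParams,
    SystemState,
    decompose,
    equilibrium,
    ode_rhs,
    p_mort,
    solve_constant,
    solve_decaying,
)
from conftest import draw_params


class TestModelParams:
    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(k1=1, c3=0.0, k_bac=1, k_TE=1, k_NTE=1, kappa=1)
        with pytest.raises(ValueError):
            ModelParams(k1=-1, c3=1, k_bac=1, k_TE=1, k_NTE=1, kappa=1)

    def test_array_round_trip(self, rng):
        p = draw_params(rng)
        assert ModelParams.from_array(p.as_array()) == p


class TestOdeRhs:
    def test_unirradiated_equilibrium_is_stationary(self, rodent_params):
        state = SystemState(t=0, Pa=0.0, Y=rodent_params.background_yield)
        dPa, dY = ode_rhs(state, R=0.0, params=rodent_params)
        assert dPa == 0.0
        assert dY == pytest.approx(0.0, abs=1e-15)

    def test_saturated_activation_decays_at_c3(self, plant_params):
        for R in (0.0, 10.0, 1e4):
            dPa, _ = ode_rhs((1.0, 0.2), R, plant_params)
            assert dPa == pytest.approx(-plant_params.c3)

    def test_termwise_definition(self, rng):
        p = draw_params(rng)
        Pa, Y, R = 0.3, 1.7, 42.0
        dPa, dY = ode_rhs((Pa, Y), R, p)
        assert dPa == pytest.approx(p.k1 * R * (1 - Pa) - p.c3 * Pa)
        assert dY == pytest.approx(
            p.k_bac + p.k_TE * R + p.k_NTE * Pa - p.kappa * Y
        )


class TestSolveConstant:
    def test_time_zero_collapses_to_pre_exposure_equilibrium(self, rng):
        for _ in range(10):
            p = draw_params(rng)
            s = solve_constant(p, Rc=37.0, t=0.0)
            assert s.Pa == pytest.approx(0.0, abs=1e-9)
            assert s.Y == pytest.approx(p.background_yield, rel=1e-6)

    def test_zero_dose_rate_stays_at_background(self, rodent_params):
        t = np.linspace(0.0, 30.0, 7)
        s = solve_constant(rodent_params, Rc=0.0, t=t)
        assert np.allclose(s.Pa, 0.0)
        assert np.allclose(s.Y, rodent_params.background_yield)

    def test_negligible_deactivation_saturates_activation(self):
        p = ModelParams(k1=1.0, c3=1e-12, k_bac=0.1, k_TE=1e-6, k_NTE=0.1,
                        kappa=0.5)
        s = solve_constant(p, Rc=5.0, t=50.0)
        assert s.Pa == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_adaptive_integration(self, rng):
        for _ in range(20):
            p = draw_params(rng)
            Rc = float(10 ** rng.uniform(-2, 4))
            if abs(p.k1 * Rc + p.c3 - p.kappa) < 1e-6 * p.kappa:
                continue
            grid = np.linspace(0.0, 20.0, 9)
            fit = DoseDecayFit(ln_R0=float(np.log(Rc)), lam=0.0)
            traj = solve_decaying(p, fit, grid)
            s = solve_constant(p, Rc, grid)
            # absolute below unit magnitude, relative above: an absolute
            # 1e-6 on a yield of several hundred would be tighter than the
            # integrator's own relative tolerance
            scale = np.maximum(1.0, np.abs(s.Y))
            assert np.max(np.abs(traj.Y - s.Y) / scale) < 1e-6
            assert np.max(np.abs(traj.Pa - s.Pa)) < 1e-6

    def test_degenerate_denominator_raises(self):
        # X1 = k1*Rc + c3 == kappa exactly
        p = ModelParams(k1=0.1, c3=0.5, k_bac=0.01, k_TE=1e-6, k_NTE=0.1,
                        kappa=1.5)
        with pytest.raises(DegenerateDenominatorError, match="numeric"):
            solve_constant(p, Rc=10.0, t=1.0)


class TestEquilibrium:
    def test_zero_dose_rate(self, plant_params):
        Pa_eq, Y_eq = equilibrium(plant_params, 0.0)
        assert Pa_eq == 0.0
        assert Y_eq == pytest.approx(plant_params.background_yield)

    def test_rodent_background_mortality(self, rodent_params):
        _, Y_eq = equilibrium(rodent_params, 0.0)
        assert Y_eq == pytest.approx(0.0223, abs=5e-4)
        assert p_mort(Y_eq) == pytest.approx(0.022, abs=5e-4)

    def test_long_time_limit_of_transient(self, rng):
        for _ in range(10):
            p = draw_params(rng)
            Rc = float(10 ** rng.uniform(-2, 3))
            X1 = p.k1 * Rc + p.c3
            if abs(X1 - p.kappa) < 1e-6 * max(X1, p.kappa):
                continue
            t_long = 10.0 / min(X1, p.kappa)
            s = solve_constant(p, Rc, t_long)
            Pa_eq, Y_eq = equilibrium(p, Rc)
            assert s.Pa == pytest.approx(Pa_eq, rel=1e-4)
            assert s.Y == pytest.approx(Y_eq, rel=1e-4)

    def test_well_defined_where_transient_formula_degenerates(self):
        p = ModelParams(k1=0.1, c3=0.5, k_bac=0.01, k_TE=1e-6, k_NTE=0.1,
                        kappa=1.5)
        Pa_eq, Y_eq = equilibrium(p, 10.0)  # X1 == kappa; no error expected
        assert 0 < Pa_eq < 1 and Y_eq > 0

    def test_yield_nondecreasing_in_dose_rate(self, plant_params, rodent_params):
        grid = np.logspace(-3, 5, 17)
        for p in (plant_params, rodent_params):
            ys = [equilibrium(p, R)[1] for R in grid]
            assert np.all(np.diff(ys) >= -1e-15)


class TestPMort:
    def test_anchor_values(self):
        assert p_mort(0.0) == 0.0
        assert p_mort(0.0223) == pytest.approx(0.02205, abs=1e-4)
        assert p_mort(50.0) == pytest.approx(1.0, abs=1e-12)

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            p_mort(-0.1)

    def test_strictly_increasing_and_bounded(self):
        y = np.linspace(0, 30, 301)
        p = p_mort(y)
        assert np.all(np.diff(p) > 0) or np.all(p[:-1] <= p[1:])
        assert p.min() == 0.0 and p.max() < 1.0


class TestSolveDecaying:
    def test_near_zero_decay_matches_constant_solution(self, plant_params):
        fit = DoseDecayFit(ln_R0=np.log(100.0), lam=1e-9)
        grid = np.linspace(0.0, 10.0, 21)
        traj = solve_decaying(plant_params, fit, grid)
        s = solve_constant(plant_params, 100.0, grid)
        assert np.max(np.abs(traj.Y - s.Y)) < 1e-6

    def test_negligible_initial_dose_rate_stays_at_background(self, rodent_params):
        fit = DoseDecayFit(ln_R0=-60.0, lam=0.3)
        traj = solve_decaying(rodent_params, fit, np.linspace(0, 10, 11))
        assert np.allclose(traj.Y, rodent_params.background_yield, rtol=1e-6)

    def test_reproduces_reported_site3_mortality(self, rodent_params):
        fit = DoseDecayFit(ln_R0=1.36, lam=0.28)
        traj = solve_decaying(rodent_params, fit, np.array([0.0, 10.0]))
        assert traj.P_mort[-1] == pytest.approx(0.218, abs=0.005)

    def test_invalid_grid_rejected(self, rodent_params):
        fit = DoseDecayFit(ln_R0=1.0, lam=0.1)
        with pytest.raises(ValueError):
            solve_decaying(rodent_params, fit, np.array([2.0, 1.0]))

    def test_activation_probability_stays_in_unit_interval(self, plant_params):
        fit = DoseDecayFit(ln_R0=11.13, lam=0.5)
        traj = solve_decaying(plant_params, fit, np.linspace(0, 20, 201))
        assert traj.Pa.min() >= 0.0 and traj.Pa.max() <= 1.0


class TestDecompose:
    def test_channels_sum_to_total(self, rng):
        for _ in range(10):
            p = draw_params(rng)
            fit = DoseDecayFit(ln_R0=float(rng.uniform(0, 8)),
                               lam=float(rng.uniform(0, 0.5)))
            grid = np.linspace(0.0, 15.0, 16)
            traj = decompose(p, fit, grid)
            total = solve_decaying(p, fit, grid)
            assert np.max(np.abs(
                traj.Y_bac + traj.Y_TE + traj.Y_NTE - total.Y
            )) < 1e-6 * (1 + np.max(np.abs(total.Y)))

    def test_tiny_nte_coupling_gives_empty_nte_channel(self, plant_params):
        p = ModelParams(**{**plant_params.to_dict(), "k_NTE": 1e-300})
        fit = DoseDecayFit(ln_R0=5.0, lam=0.2)
        traj = decompose(p, fit, np.linspace(0, 10, 11))
        assert np.max(np.abs(traj.Y_NTE)) < 1e-12

    def test_background_channel_constant_from_equilibrium_start(self, rodent_params):
        fit = DoseDecayFit(ln_R0=2.89, lam=0.24)
        traj = decompose(rodent_params, fit, np.linspace(0, 10, 11))
        assert np.allclose(traj.Y_bac, rodent_params.background_yield, rtol=1e-6)

    def test_te_source_rate_below_nte_rate_at_high_constant_dose(self, plant_params):
        # at 10,000 µGy/h the targeted channel still forms damage more
        # slowly than the non-targeted channel near equilibrium
        Rc = 1e4
        Pa_eq, _ = equilibrium(plant_params, Rc)
        assert plant_params.k_TE * Rc < plant_params.k_NTE * Pa_eq

    def test_frame_export_has_channel_columns(self, rodent_params):
        fit = DoseDecayFit(ln_R0=1.36, lam=0.28)
        frame = decompose(rodent_params, fit, np.linspace(0, 5, 6)).to_frame()
        assert {"t_years", "P_mort", "Y_TE", "Y_NTE", "Y_bac"} <= set(frame.columns)


class TestFastPropagator:
    def test_matches_reference_integrator(self, rng):
        worst = 0.0
        for _ in range(20):
            p = draw_params(rng)
            lnR0 = float(rng.uniform(0, 11))
            lam = float(rng.uniform(0, 0.5))
            times = np.array([1.0, 2.0, 5.0, 10.0])
            prop = Propagator([lnR0], [lam], times, np.zeros(4, int))
            fast = prop.mortality(p.as_array())
            ref = solve_decaying(
                p, DoseDecayFit(ln_R0=lnR0, lam=lam),
                np.concatenate([[0.0], times]),
            ).P_mort[1:]
            worst = max(worst, float(np.max(np.abs(fast - ref))))
        assert worst < 5e-5

    def test_exact_for_constant_dose_rate(self, plant_params):
        times = np.array([1.0, 4.0, 9.0])
        prop = Propagator([np.log(50.0)], [0.0], times, np.zeros(3, int))
        s = solve_constant(plant_params, 50.0, times)
        fast = prop.mortality(plant_params.as_array())
        assert np.max(np.abs(fast - p_mort(s.Y))) < 1e-9
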