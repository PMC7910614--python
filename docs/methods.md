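# Methods

## Model and assumptions

The kinetics track a chronically exposed population with two mean-field
variables: the probability `P_a` that cells are in a non-targeted-effects
(NTE) activated state, and the mean yield `Y` of lethal events per embryo.
Activation is driven by dose rate at rate `k1·R·(1 − P_a)` and decays at
`c3·P_a`; damage forms from background (`k_bac`), targeted energy
deposition (`k_TE·R`) and the activated state (`k_NTE·P_a`), and is removed
at `κ·Y`.  Mortality is `P_mort = 1 − exp(−Y)` (Poisson probability of at
least one lethal event).  The model is deliberately minimal: no spatial
structure, no explicit signalling mechanism, no radionuclide transport —
the exponential dose-rate decay `R(t) = R0·e^{−λt}` absorbs all
environmental dynamics into two per-location constants.

Unit convention: dose rate is carried in µGy/h and time in years
**without** an hours-to-years conversion, i.e. `k1` and `k_TE` are "per
(µGy/h) per year" couplings.  This is the convention under which the
published best-fit parameter sets reproduce the published per-observation
fitted mortalities (verified for all 47 fixture rows to ≤ ±0.002); carrying
R in µGy/year instead saturates the activation state everywhere and cannot.

Initial conditions are the pre-accident equilibrium `P_a(0) = 0`,
`Y(0) = k_bac/κ` at the accident time `t = 0`.  This choice reproduces the
background-site fitted values (e.g. the vole background mortality 0.022)
and all checked worked examples.

## Dose-decay estimation

Each observation series (a location, or a sub-series where one site mixes
background and contaminated sampling campaigns) gets `(ln R0, λ)` from a
Huber M-regression of ln dose rate on time: ψ tuning constant 1.345, scale
re-estimated each iteration as median |residual| / 0.6745, started from
ordinary least squares, convergence when the relative coefficient change
drops below 1e−8, at most 200 iterations.  The implementation is the
package's own compact IRLS because the textbook recipe collapses to zero
robust scale on exactly-collinear-plus-outlier data, which library
implementations answer with NaNs; on regular data it matches both R's
`MASS::rlm` and statsmodels `RLM` to ≤ 1e−4 (both are kept as independent
cross-check oracles in the tests).  Series with fewer than two distinct
sampling times fall back to `λ = 1e−3 yr⁻¹` (near zero, kept positive so
the model solution stays non-singular) with `R0` the arithmetic mean of the
measured rates.

Known reproducibility limit: the packaged tables also store the originally
reported per-series intercept/slope columns, and for several multi-point
series no standard robust estimator — Huber, MM, or least-trimmed-squares,
in R or Python — reproduces those stored values from the *printed* dose
rates.  The two-point contaminated sub-series of the vole "Site 2" proves
why: any line estimator returns the exact interpolant through two points,
(−0.64, 0.17), yet the stored line is (−0.69, 0.16), so the original
regressions must have used unrounded dose rates that were never published.
The package therefore treats the stored regression columns as reference
data (reproduced exactly for fallback and exactly-collinear series,
approximately otherwise), while the pipeline always regresses on the
observation table it is given.  Downstream results are insensitive to this:
forward predictions with either line agree to well under 0.01 mortality.

Huber M-estimation is robust to dispersed gross outliers (the tests verify
exact-line recovery with up to 30% contamination) but, like any monotone
M-estimator, can be defeated by clustered outliers at consecutive
high-leverage design points; that failure mode is inherent, not a defect.

## Numerical solution

`solve_constant` evaluates the closed-form constant-dose-rate solution; its
transient formula genuinely degenerates when `k1·Rc + c3 = κ` (guard width
1e−12 relative), in which case the numeric path is prescribed.  The
equilibrium is evaluated in the cancellation-free form
`Y_eq = (k_bac + k_TE·Rc + k_NTE·P_a,eq)/κ`, which is algebraically
identical to the ratio form with the `(X1 − κ)` denominator but remains
well defined at the crossing — that singularity is removable, so no error
is raised there.

`solve_decaying` and `decompose` integrate with adaptive LSODA (rtol 1e−8,
atol 1e−10, analytic Jacobian); the activation equation is stiff whenever
`k1·R ≫ κ`, which the plant parameter set reaches at high dose rates.
`decompose` integrates the three damage sources as separate channels with
the shared removal term; because the Y equation is linear with additive
sources, the channels sum to the total yield to integrator tolerance (a
property test).

The fitting objective cannot afford ~6 ms per LSODA evaluation across
multi-start optimization and bootstrap resampling, so it runs on a
piecewise-analytic propagator: each sub-step replaces the dose rate by its
exact average over the step and applies the exact constant-dose-rate affine
update.  The scheme is unconditionally stable for arbitrarily stiff
activation, exact when λ = 0, second-order in the step size, and a
Richardson combination of one grid with its midpoint refinement raises it
to fourth order: worst-case disagreement with LSODA over random parameter
draws is ~3e−5 in mortality at the fitting resolution (λ·h ≤ 0.04) and
~3e−7 at the synthetic-truth resolution (λ·h ≤ 0.01).  Reported fit
results (`FitResult.fitted`, R², RMSE) are always recomputed with the
reference integrator.

## Fitting

Objective: unweighted sum of squared residuals on the mortality-probability
scale — the scale the original goodness-of-fit statistics are reported on;
no weighting is applied.  The six rate constants are optimized in log10
space (they span nine decades across the two species) inside a shared box
of [1e−9, 1e3] per parameter, by `scipy.optimize.least_squares` (trust
region reflective, finite-difference Jacobian, tolerances 1e−8) from 32
Latin-hypercube starting points (seeded; the fit is bit-reproducible).
The original study's customized iterative optimizer was never published,
so exact reproduction of its parameter estimates is not expected — nor
needed: several parameters are only identified in combinations (`k1/c3`,
`k_bac/κ`), and what is reproducible is the fitted-value surface (plant
R² 0.43, RMSE 0.044; rodent R² 0.84, RMSE 0.029, all matching the reported
footers) and the well-identified NTE coupling `k_NTE`.

Bootstrap: case resampling of observations with replacement (no blocking by
location), implemented as integer row weights so the exposure series are
propagated once per objective evaluation; each replicate refits from the
best-fit parameters as the single start (tolerance 1e−8, ≤ 60 evaluation
budget by default), and the 2.5th/97.5th percentiles of the replicate
estimates form the 95% interval.  On the 12-row vole table a minority of
replicates that drop the background rows wander to alternative optima with
large `k_NTE`, giving a heavy right tail in the percentile interval; this
is a genuine property of case-resampling so small a table, and is reported
as computed.

Datasets with fewer observations than parameters are fitted but flagged
`identifiable = False`.

## Synthetic data

The generator emulates the field-study structure: by default 12 locations,
each with a uniformly drawn `ln R0 ∈ [0, 11]` (ln µGy/h) and
`λ ∈ [0, 0.5]` yr⁻¹ — spanning the ranges observed across both packaged
tables — sampled at 1–6 whole-year times in [1, 10] years, with true
mortality from the model at rodent-scale generating parameters.  The
default observation-noise model is binomial with 50 embryos scored per
observation, because mortality data are proportions of scored embryos; a
Gaussian model (sd 0.02, clipped to [0, 1]) is retained for
variance-sensitivity checks, and a noise-free mode for self-consistency
tests.  No published noise model exists for these data; the binomial choice
and the recovery targets (noise-free prediction RMSE < 1e−3; `k_NTE`
within a factor of 2 in ≥ 8/10 replicates; 200-replicate bootstrap CI
covering the generating `k_NTE` in ≥ 80% of 20 repetitions) were fixed by
simulation before the acceptance suite was frozen.

What passing these simulations shows: the pipeline recovers what the model
and noise process can identify.  What it does not show: robustness to the
features real field data add — dosimetry error, unmodelled covariates
(weather, ecology, land use), non-binomial overdispersion, and
non-exponential dose-rate histories.

## Scenario predictions

Constant-rate dose-response tables evaluate the system at `t = 20` years
(near equilibrium for both parameter sets) across a dose-rate grid;
decaying-exposure time courses use `λ = ln 2 / halving time` on a dense
grid (401 points by default).  Channel contributions on the mortality scale
are defined as `p_mort(Y_bac + Y_channel) − p_mort(Y_bac)` — the excess
mortality the channel would cause on top of background alone; channels are
exactly additive on the yield scale but not after the concave Poisson link,
so the TE and NTE curves need not sum to the total, and qualitative
TE-vs-NTE comparisons are invariant to this monotone choice.  Background
subtraction is on by default.  `peak_time` refines the grid argmax with a
local quadratic and flags a maximum on the final grid point as censored at
the horizon.

Problem sizes used by the test suite and the acceptance script (40-row
synthetic designs, 10 recovery replicates, 20 coverage repetitions with 200
bootstrap replicates, 100-draw oracle checks) match the sizes the recovery
targets were calibrated at.

## Known limitations

- The stored per-series regression columns are only partially reproducible
  from the printed dose rates (see above); the discrepancy is in the
  available data, not the estimator.
- `k1`, `c3`, `k_TE` and `κ` are weakly identified on datasets of this
  size; only predictions and `k_NTE` (and the ratios `k1/c3`, `k_bac/κ`)
  should be interpreted.
- The bootstrap interval for a 12-row table is heavy-tailed (see Fitting).
- The mean-field two-variable model cannot represent dose-rate-dependent
  repair modulation, spatially structured signalling, or mixed radiation
  qualities.
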