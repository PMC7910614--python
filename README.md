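# radnte

Modelling of multigenerational radiation effects through **targeted (TE)**
and **non-targeted (NTE)** damage kinetics, applied to embryonic mortality
in wild populations chronically exposed after a nuclear accident.

Field surveys from the Chernobyl region recorded a puzzling pattern:
embryonic mortality in plants (*Arabidopsis thaliana*) and rodents
(*Clethrionomys glareolus*, bank vole) stayed elevated — or kept rising —
for many generations while ambient dose rates fell by orders of magnitude.
Classical target theory (damage proportional to dose delivered to the cell
nucleus) cannot produce that shape.  Non-targeted effects — stress states
propagated by inter-cell signalling and inherited epigenetically — can:
once a population is "switched on", damage keeps forming until the stressed
state decays away.

This package is for quantitative radiobiologists and ecotoxicologists who
want a tested, reusable implementation of that model: data containers for
field observation tables, per-location dose-rate-decay estimation, model
fitting with bootstrap confidence intervals, scenario prediction with TE/NTE
decomposition, and a synthetic-data generator for method validation.

## The model

State variables: `P_a(t)`, the mean probability that cells are in the
NTE-activated (stressed) state, and `Y(t)`, the mean yield of lethal events
per embryo.  With dose rate `R(t)` in µGy/h and time in years,

```
dP_a/dt = k1·R·(1 − P_a) − c3·P_a
dY/dt   = k_bac + k_TE·R + k_NTE·P_a − κ·Y
```

The six positive rate constants: `k1` (activation per unit dose rate),
`c3` (deactivation, yr⁻¹), `k_bac` (background damage formation, yr⁻¹),
`k_TE` (targeted damage per unit dose rate), `k_NTE` (damage formation per
unit activated fraction, yr⁻¹), `κ` (damage removal, yr⁻¹).  Observed
mortality is the probability of at least one lethal event under a Poisson
assumption:

```
P_mort = 1 − exp(−Y)
```

Post-accident exposure decays as `R(t) = R0·exp(−λt)`, with `(ln R0, λ)`
estimated per location by Huber robust regression of ln dose rate on time
(locations with a single sampling time fall back to `λ = 1e−3 yr⁻¹` and the
mean measured rate).  At constant dose rate the system has a closed-form
solution and equilibrium, used as oracles; under decaying exposure it is
integrated numerically.  Parameters are estimated by multi-start bounded
least squares on the mortality scale, with case-bootstrap percentile
confidence intervals.

## Worked example

```python
import radnte

rodent = radnte.load_fixture("rodent")          # 12 observations, 3 sites
decay = radnte.fit_dataset(rodent)              # per-series (ln R0, lambda)
fit = radnte.fit_model(rodent, decay, radnte.FitConfig(n_starts=32, seed=1))
print(f"r2={fit.r2:.3f} rmse={fit.rmse:.4f} k_NTE={fit.params.k_NTE:.4f}")
```

prints

```
r2=0.845 rmse=0.0292 k_NTE=0.0258
```

i.e. the model explains 84.5% of the variance in the vole embryonic
mortality probabilities with a root-mean-square residual of about 0.03, and
the fitted NTE coupling converts the activated fraction into roughly 0.026
lethal events per embryo per year.  Scenario predictions then show the
species contrast:

```python
plant = radnte.ModelParams.from_dict(
    radnte.load_reference_params("plant")["params"])
course = radnte.time_course_decaying(plant, R0=1e4, halving_time=1.0,
                                     horizon=20.0)
print(radnte.peak_time(course))
```

```
PeakEstimate(time=6.170222787608588, value=0.09401306851792592, censored=False)
```

With plant-scale kinetics the radiation-induced mortality peaks about 6
years after the accident and then declines; with rodent-scale kinetics the
same exposure scenario is still rising at 10 years (the peak is censored at
the simulation horizon) because the stressed state deactivates and damage
is removed about five orders of magnitude more slowly.

A command-line interface mirrors these stages
(`radnte decay-fit | fit | bootstrap | predict | scenario | simulate`).

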