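# persistforage

Linking a marine predator's horizontal movement behaviour to prey fields
and diving effort, from raw satellite telemetry to validated mixed-effects
estimates — with a synthetic-data generator so the whole pipeline is
testable end to end with known ground truth.

## Who this is for

Movement ecologists and biologging statisticians who want to (a) estimate
*move persistence* — a continuous behavioural index γ_t ∈ (0, 1) along an
animal's track, where low values indicate area-restricted search (a common
foraging proxy) and high values indicate directed travel — (b) model it
against gridded habitat covariates such as prey biomass, prey diversity,
bathymetry and SST, and (c) check whether the inferred "foraging" signal
is corroborated by diving behaviour.

## The model

Tracks are regularized to a 4-h lattice and differenced into local-km
displacements `d_t`.  The process model is a first-difference correlated
random walk whose memory is the latent persistence:

    d_t = γ_t · d_{t−1} + η_t,          η_t ~ N(0, Σ_d)
    logit(γ_{t,k}) = β₀ + b_k + β₁ x_{t,1,k} + … + β_n x_{t,n,k} + ε_t

with individual random intercepts `b_k ~ N(0, σ_b²)` and step noise
`ε_t ~ N(0, σ_γ²)`.  Covariates are z-scored within calendar year, so the
`β_j` are per-SD effects on the log-odds of persisting.  The marginal
likelihood integrates `(b_k, ε_t)` by nested adaptive Gauss–Hermite
quadrature seeded at the Laplace mode (a plain Laplace option exists) and
is maximized by quasi-Newton ML.  The intercept-only model estimates
k = 6 parameters (β₀, σ_b, σ_γ, and three for Σ_d); each covariate adds
one.  Candidate models are ranked by AIC with a parsimony rule: among
models within 2 ΔAIC of the best, the one with fewest parameters wins.

Around this core the package provides:

- `simdata` — seeded generator for prey grids (8 species, 0.5°, yearly),
  bathymetry/SST (0.01°), weekly ice, Argos-like tracks with class-specific
  error, and dive records with configurable coupling to γ;
- `preprocess` — open-water season from the 50% ice-concentration
  crossings, segmentation at >12-h gaps, <50-fix removal, 30 km/h speed
  filter, and a continuous-time correlated-random-walk Kalman smoother
  onto the exact 4-h lattice;
- `covariates` — cell matching, Simpson's diversity D = 1 − Σ(nᵢ/N)²,
  total biomass, within-year scaling;
- `mpmm` — the move-persistence mixed-effects model, AIC ranking,
  leave-one-individual-out cross validation, one-step-ahead residuals;
- `divevalid` — eight dive metrics in ±2-h windows and AR1
  random-intercept linear mixed models relating γ, dive metrics, prey and
  bathymetry;
- `pipeline` / `persistforage` CLI — one seeded, fully reproducible run.

## Worked example

```python
import numpy as np
from persistforage import simdata, mpmm

cfg = simdata.SimConfig(n_individuals=25, steps_per_track=100,
                        covariate_names=("bathy",), true_beta=(0.5, -0.5),
                        sigma_b=0.3, sigma_gamma=0.3, seed=100)
grids = simdata.gen_grids(cfg)
truths, raws = simdata.simulate_movement(cfg, grids)
data = mpmm.build_data_from_truth(truths, ("bathy",))
fit = mpmm.fit_mpmm(data, "gamma ~ bathy + (1|id)")
print(f"beta_bathy = {fit.beta[1]:.3f} (SE {fit.beta_se[1]:.3f})")
print(f"sigma_b = {fit.sigma_b:.3f}  k = {fit.k}  AIC = {fit.aic:.1f}")
```

prints

```
beta_bathy = -0.509 (SE 0.196)
sigma_b = 0.308  k = 7  AIC = 14436.7
```

The simulated deep-water preference (−0.5 on the logit scale per field-SD
of bathymetry) is recovered within one standard error; k = 7 is the
six-parameter null model plus the one bathymetry slope.  A full pipeline
run — simulation, preprocessing, covariate matching, the 14-model
candidate set, LOO cross validation, and the dive-metric validation
battery — is one command:

```bash
persistforage run --seed 1 --out runs/demo
```

which takes a few minutes at the default study size (pass a JSON
`--config` with fewer individuals for a quick look) and writes a ranked `model_table.csv`, per-location `gamma_hat.csv`,
`relations.csv` (slope, SE, p per response–predictor pair), a JSON
manifest with per-stage counts, and a readable `report.txt`.

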