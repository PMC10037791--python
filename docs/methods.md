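# Methods

## Model

Move persistence γ_t is a continuous behavioural index in (0, 1): the
degree to which the current 4-h displacement continues the previous one.
Displacements are modelled as a first-difference correlated random walk in
a local tangent-plane km coordinate system,

    d_t = γ_t d_{t−1} + η_t,    η_t ~ N(0, Σ_d),

with Σ_d a full 2×2 covariance (two SDs and one correlation, three free
parameters).  Persistence follows a logit-linear mixed model,

    logit(γ_{t,k}) = β₀ + b_k + Σ_j β_j x_{t,j,k} + ε_t,

with individual random intercepts b_k ~ N(0, σ_b²) and iid step noise
ε_t ~ N(0, σ_γ²).  The random intercept enters additively; a printed
subtraction of a zero-mean symmetric deviation is the same model, and the
additive form is conventional.  Random slopes are deliberately not
supported.  The intercept-only model therefore estimates six parameters
(β₀, σ_b, σ_γ, and three for Σ_d), and every added fixed covariate adds
exactly one — this accounting is what the `k` column of the ranked model
table reports.

Segments belonging to the same individual share one b_k.  The first
displacement of each segment is conditioned on (no γ is defined for it),
so a segment with L lattice positions contributes L − 2 modelled steps.

## Estimation

The latent vector per individual is (b_k, ε_1…ε_T).  Conditional on b_k
the ε_t are independent, so the joint negative log-density has an
arrowhead Hessian; an inner Newton solve with Schur-complement updates
finds the mode in O(T) per iteration.  The marginal likelihood is then
computed by nested one-dimensional adaptive Gauss–Hermite quadrature:
each ε_t integral is a 1-D AGH rule (7 nodes) centred at its conditional
mode, nested inside a 7-node AGH rule over b_k centred at the joint-mode
b with the Laplace (Schur) curvature.  A plain Laplace value is available
(`method="laplace"`); we found it biased by up to ~2×10⁻² log-likelihood
units on very short series (checked against node-converged tensor-product
quadrature), while the nested rule agrees with brute-force quadrature to
~10⁻⁷, at a constant-factor cost.  Fitting is two-stage quasi-Newton
(L-BFGS-B): a fast Laplace pass from the documented starting values
(β = 0, σ_b = σ_γ = 0.5, Σ_d from the empirical displacement covariance),
then refinement of the quadrature objective.  Standard errors come from
the inverse numerical Hessian of the negative marginal log-likelihood,
with difference steps (2×10⁻³) sized well above the inner-solver noise
floor; CIs are Wald ±1.96 SE.

Model selection uses AIC with a parsimony rule: among candidates within
2 ΔAIC of the minimum, the fewest-parameter model is selected (ties on k
broken by lower AIC).  Unconverged fits are refused by the ranking.
Leave-one-individual-out cross validation refits the chosen model once
per excluded individual and reports the fraction of refitted fixed-effect
estimates inside the full model's 95% CIs.  One-step-ahead residuals use
the fixed-plus-random-effect prediction of γ (ε_t predicted at zero, so
nothing from the current displacement leaks into its own prediction),
standardized per coordinate by the Σ_d SDs.

## Preprocessing

Open-water season: break-up is the linearly interpolated time of the last
downward crossing of 50% ice concentration after which the weekly series
stays below 50% until the freeze-up ascent; freeze-up is symmetric.  A
sample exactly at 50% counts as the crossing.  Mid-season blips above the
threshold push break-up to the last qualifying crossing — the crossing
rule needs a convention for re-freezing excursions and this is the one we
fixed.

Tracks are windowed to the season, split at transmission gaps strictly
longer than 12 h, and segments with fewer than 50 fixes are dropped.  The
30 km/h speed limit is applied as a greedy pre-filter (first fix always
kept; any fix implying a faster speed from the last retained fix is
removed), which makes it idempotent; applying the limit before rather
than inside the state-space model suppresses the same outliers with a
simpler likelihood.

Regularization fits a continuous-time correlated random walk
(Ornstein–Uhlenbeck velocity, integrated position; exact discretization
over irregular intervals) per segment by ML Kalman filtering, with
Argos-class observation-error SD ratios fixed to the simulator defaults
and one overall error scale estimated — full per-class estimation is
unidentifiable on short segments.  Rauch–Tung–Striebel smoothing returns
positions and SDs on the exact 4-h lattice anchored at the first fix time
rounded up to the whole hour.  Estimation runs in two stages (smoothed
positions feed the persistence model as data); joint estimation of
location error and behaviour is out of scope.

## Covariates

Cells are half-open, [origin, origin + resolution), in both axes; a point
on a shared edge belongs to the cell whose origin it is.  Each location
takes the 0.5° prey cell of its calendar year, the 0.01° bathymetry cell,
and the 0.01° SST cell of its calendar month.  Simpson's diversity
D = 1 − Σ(nᵢ/N)² is computed from the eight matched biomasses; an
all-zero biomass vector is an error (N = 0 is undefined), not D = 0.
Covariates are z-scored within calendar year using the sample (n−1) SD
over the matched analysis rows, pooled across individuals.

A consequence worth knowing: within-dataset z-scoring measures effects
per SD *of the sampled locations*, which along short tracks is smaller
than the SD of the underlying field.  The simulator defines its true
coefficients per field-SD, so estimator-level recovery studies build
their design matrix on the simulator's scale
(`build_data_from_truth(..., rescale=False)`); the pipeline's within-year
scaling simply changes the estimand by the corresponding SD ratio.

## Synthetic data

The generator emulates a single open-water season of a coastal seal
study: 25 individuals, 100 four-hour steps, fixes every ~1.2 h on average
with occasional 13–30-h gaps, six Argos quality classes with error SDs
0.25–10 km (invented defaults, config-overridable), dive rate ~8 per 4-h
step.  Biomass fields are exponentiated Gaussian random fields (Gaussian
kernel smoothing of white noise; the per-species mean is preserved
exactly by the −s²/2 correction), bathymetry is a smooth strictly
negative surface between 20 and 250 m depth, SST is an annual cosine
cycle peaking in August plus a smooth spatial anomaly, and weekly ice
follows a logistic melt (midpoint ~day 170) and re-freeze (~day 330).
Tracks are simulated from exactly the process model above, with
covariates standardized by field moments; boundary exits reflect back
into the domain (kept rare by the domain size relative to track extent).
Dive counts per step are Poisson with log-rate linear in γ_t (coefficient
`dive_coupling`; negative values concentrate dives at low persistence);
dive depths are Beta(2,2) fractions of the local water column, so depth
constraints hold by construction.

What the generator does not emulate: haul-out and resting behaviour,
tidal or ice-drift advection, t-distributed Argos errors, multi-year
prey dynamics, or prey–predator feedback.  Passing tests therefore show
the pipeline recovers what this generative world encodes — not that the
model is correct for any particular real dataset.

## Numerical choices and degenerate inputs

- Inner Newton: curvature clipped at 1e-9, backtracking halving line
  search, stop when the gradient ∞-norm falls below 1e-9 or no measurable
  decrease is possible.
- Variance parameters are fitted on log scale, correlations via atanh, so
  every reachable parameter point is feasible.  The logit-scale SDs σ_b
  and σ_γ are additionally bounded above by 2: beyond that the
  logistic-normal law on γ turns U-shaped (mass piles onto 0 and 1), the
  model degenerates into an unidentifiable per-step switch with a
  spurious likelihood spike, and mode-centred integration loses its
  unimodality assumption.  The bound is a feasibility constraint of the
  bounds-constrained optimizer, far above any plausible estimate.
- The AR1 mixed model profiles the fixed effects by GLS inside an ML
  search over (atanh φ, log σ_u, log σ_e); after L-BFGS-B a Nelder–Mead
  polish from the incumbent guards against stalled line searches.  The
  slope SE is the GLS information (X'V⁻¹X)⁻¹; p-values are Wald and
  reported raw (no multiplicity correction).
- Dive-to-location ties at exactly ±2 h go to the later location; water
  column proportions above 1 (dive deeper than charted) are capped at 1
  and counted.
- Degenerate inputs raise typed errors rather than guessing: unsorted
  fixes, all-zero biomass, constant within-year covariates, ice series
  that never cross the threshold.

## Problem sizes

Simulation studies in the tests and the acceptance script use 20
replicates of 25 individuals × 100 steps for coefficient recovery and
selection, one 25-individual dataset for leave-one-out, 50 segments for
the smoother comparison, 40 groups × 50 observations for the AR1 LMM
recovery, and 5–8 individuals for end-to-end pipeline runs — sizes chosen
so that each study carries enough information for its property while the
whole battery remains a desk-scale computation.

## Known limitations

- σ_γ is weakly identified when displacement noise is large relative to
  the persistence signal (short series, coarse step); its ML estimate can
  sit near zero without harming fixed-effect inference.
- Prey covariates are piecewise-constant on 0.5° cells, so they vary
  little along a short track and their effects are estimated mostly from
  between-individual contrasts — a real limitation of coarse prey fields
  that the synthetic world reproduces.
- The AR1 correlation in the validation LMM is on observation order
  within track, which equals time lag only on the regular lattice (rows
  dropped for missing metrics shorten the effective lag).
- LOO coverage is a stability diagnostic, not a calibrated frequentist
  coverage statement.
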