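# Methods

## Scope and data model

The package validates an external probabilistic prognostic model against a
cohort of binary outcomes. A cohort row is `(Y_i, p_i, X_i)`: outcome
`Y_i ∈ {0, 1}` with **1 = alive at the 10-year horizon** (all odds ratios
are therefore odds of surviving), an external prediction `p_i ∈ (0, 1)`, and
categorical covariates. The external model is a black box: only `p_i`
enters any computation. Records with a missing outcome or prediction are
excluded at read time and counted; missing covariate values become an
explicit `missing` level, because subgroup tables subset per covariate
independently and should not lose patients over an unrelated covariate.
There is no survival-time (censored) model anywhere: the external tool
provides only a probability, not a hazard, so a logistic treatment of the
fixed-horizon outcome is the natural frame, and it is what makes the offset
construction below possible.

Predictions are clipped to `[1e-6, 1 − 1e-6]` before any logit; actuarial
calculators round their output and can emit exactly 0 or 1, and the clip
bound is far below any plausible prediction granularity.

## Calibration

The recalibration model is `logit P(Y_i = 1) = α + β·logit(p_i)`, with
H₀: (α, β) = (0, 1). This tests calibration without grouping, which matters
at validation sizes of a few hundred where risk-grouped comparisons leave
tiny cells. Design choices:

- **Joint statistic.** Likelihood ratio with 2 df against the fully
  constrained model `logit = logit(p_i)` (offset only, zero free
  parameters), whose log-likelihood is evaluated directly. LR is
  better-behaved than Wald at subgroup sizes of tens of patients; a Wald
  version (`test="wald"`) is provided. The LR statistic is clipped at 0
  against floating-point negatives.
- **Intercept.** α is a free parameter. (Describing this model as
  "without intercept" is a common shorthand for the offset null; the
  fitted recalibration model itself has both α and β free.)
- **Subgroup p-values** in agreement tables reuse the same 2-df joint test
  within each subgroup. A 1-df calibration-in-the-large test (α free, β
  fixed at 1) is available via `subgroup_test="citl"`; with mean-level
  miscalibration dominating in practice the two orderings rarely differ,
  but the 2-df test is the default because it is the same hypothesis as the
  overall test.
- **Non-estimable cells.** A subgroup with a single outcome value, or one
  whose fit separates (|coefficient| > 30 on the logit scale, SE > 1e3, or
  a statsmodels separation error), is flagged and its p-value reported as
  missing — never fabricated. Empty subgroups (a declared level with no
  patients) yield an `n = 0` row with all statistics missing.
- **Binning** for calibration plots uses half-open intervals
  `[k·w, (k+1)·w)` of default width 0.05, final interval closed at 1.
  Empty bins are omitted from plot data but can be retained with count 0,
  in which case the bins tile [0, 1] exactly.

Agreement rows report mean predicted and observed survival as percentages;
`difference = predicted − observed`, so positive means over-optimism.
Internal values are unrounded; renderers round to one decimal.

## Offset models for added value

`logit P(Y_i = 1) = α + Σ β_j X_ij + logit(p_i)` with the prediction logit
as an offset (coefficient fixed at 1), so the external prediction is taken
as *a priori* information and never re-estimated. Multivariate mode fits
all variables the external model already uses together; univariate mode
fits each new candidate alone. Reports label the two modes because their
interpretations differ: in multivariate mode a significant coefficient
means the predictor-outcome association in the validation population
differs from the development population; in univariate mode it means the
predictor adds information to the external model.

- Categorical encoding is reference-level indicator coding, reference
  levels taken from the cohort schema (overridable per spec).
- Each variable gets one factor-level LR p-value (df = its non-reference
  indicator columns); per-level Wald p-values are deliberately not shown in
  default reports. CIs are Wald, `exp(β̂ ± 1.96·SE)`.
- Fitting is IRLS (statsmodels binomial GLM), tolerance 1e-8, max 100
  iterations; non-convergence and separation are surfaced as flags.
- A declared level with zero observations (an empty treatment arm) is
  dropped from the design and recorded in `dropped_levels`. A variable
  with a single *observed* level cannot enter `fit_offset_model` (error
  naming the variable); the accuracy table instead collapses such a model
  to the offset-only reference, since a constant indicator is absorbed by
  the intercept.

## Accuracy metrics

- **Predictive inaccuracy** `PI = (1/n) Σ |Y_i − π̂_i|` with `π̂_i` the
  model's in-sample fitted probability. For a constant predictor
  `π̂ = m = mean(Y)`, `PI = 2m(1 − m)` exactly — used as an oracle check.
- **Explained variation** `EV = 100·(PI_ref − PI_model)/PI_ref`, with the
  offset-only model as reference. The proportional-reduction form is used
  because it reproduces the published pairing of inaccuracy and
  explained-variation values to rounding; it can be negative when the added
  covariate worsens absolute error.
- **Bootstrap SEs**: B = 200 patient resamples with replacement by default;
  models (and, for EV, the reference) are *refitted* on every resample —
  re-evaluating fixed fits would understate the variance of the whole
  procedure. Failed resample fits are dropped and counted; more than 20 %
  failures marks the SE unreliable. A stratified (outcome-preserving)
  bootstrap is available as an option.
- **AUC** is the Wilcoxon–Mann–Whitney statistic computed from midranks
  (ties count ½), identical to the brute-force mean over positive×negative
  pairs to 1e-12. The 95 % CI uses the DeLong asymptotic variance from
  per-observation structural components; bracketed symmetric intervals are
  the convention this matches. AUC is invariant under strictly increasing
  score transforms, which is also why the offset-only model's AUC equals
  the AUC of the raw prediction.
- Evaluation is **in-sample** (apparent performance); there is no
  cross-validation or optimism correction, and reports should be read
  accordingly.

## Synthetic cohort generator

Per patient: covariates are drawn independently from per-covariate marginal
frequencies; a latent score `s_i ~ Normal(μ, σ)` gives the reported
prediction `p_i = inv_logit(s_i)` (so predictions are logistic-normal); the
true survival probability is

```
π_i = inv_logit(α_true + β_true·s_i + Σ γ(covariate effects) + Σ δ(subgroup shifts))
```

and `Y_i ~ Bernoulli(π_i)`. With no shifts/effects and (α, β) = (0, 1) the
prediction is calibrated by construction; shifts model subgroup
miscalibration of the external tool; effects model prognostic information
it lacks. The two are interchangeable in the likelihood and kept apart only
semantically. RNG is a single named `numpy` generator seeded explicitly in
every public call; no global state.

Built-in presets encode two published validation cohorts through their
level counts (used exactly, so marginals sum to 1 by construction):

- `french`: n = 435, node-negative, no mastectomy, Ki67 split stored as its
  printed counts 262/173. σ = 1.0 and μ solved (Gauss–Hermite, 80 nodes)
  so the mean prediction is 0.851; covariate effects for HER2, mitotic
  index, Ki67 and grade 3 are the logs of the reported validation odds
  ratios (≈ 0.39–0.48 for adverse levels); an age<40 shift of −1.0 encodes
  the reported youth over-optimism; α_true solved so expected survival is
  0.874 (β_true = 1).
- `dutch`: n = 247, μ solved for mean prediction 0.786, age<40 shift −1.3,
  signature effect log(8.21) ≈ 2.1, mitotic-index and grade effects from
  the reported odds ratios, α_true solved for expected survival 0.664.

The intercept/mean solvers integrate the latent normal by Gauss–Hermite
quadrature and enumerate the joint distribution of shifted covariates
(valid because covariates are independent); they are deterministic, so
profiles are reproducible without any RNG use at construction.

What the generator does **not** emulate: covariate correlation (only
marginals are published; a `joint_sampler` hook accepts a user-supplied
correlated sampler), the internal actuarial structure of the external tool,
treatment-benefit logic, or censoring. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not fidelity of any real prediction tool.

## Numerical and testing choices

- Separation thresholds: |coefficient| > 30 or SE > 1e3 on the logit scale.
- LR statistics clipped at 0; chi-square reference distributions throughout.
- Rendering is a pure function of the JSON-serialized report (dict
  iteration is sorted), so a serialized report re-renders byte-identically.
- Monte-Carlo check sizes: test size of the joint calibration test uses
  2000 cohorts of n = 435 against the 99 % binomial band around 0.05;
  parameter recovery uses 500 replicates at n = 2000 over the grid
  (α, β) ∈ {−1, 0, 1} × {0.5, 1, 2}, with mean bias bounded by 4 SE of the
  replicate mean (18 simultaneous comparisons; a 3-SE bound would carry a
  ~5 % family false-alarm rate by chance alone); offset-model null
  rejection uses 2000 replicates at n = 435.

## Known limitations

- Factor-level p-values are LR-based; published tables of this kind do not
  always state their test, so exact numerical agreement with any particular
  publication is not claimed (same for subgroup calibration p-values).
- In-sample PI/EV/AUC are optimistic for the *extended* models; the
  offset-only reference has no free parameters beyond the intercept, so the
  comparison mildly favours additions. This mirrors apparent-performance
  reporting conventions.
- The Wald CIs for odds ratios can be poor at very small cell counts;
  profile-likelihood CIs are not implemented.
- The generator's independent covariates understate real-world confounding
  between, e.g., grade and proliferation markers.
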