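# Methods

This note documents the models and procedures epifluct implements, the
choices made where the design was genuinely open, and what the synthetic
data do — and do not — establish about real methylation arrays.

## Problem setting

Epigenetic clocks estimate age from DNA methylation beta values (fraction
methylated, in [0, 1]) at a fixed CpG panel. When the same person is sampled
repeatedly over days to months, the estimated age fluctuates even without
any intervention. epifluct quantifies that within-person fluctuation,
attributes it to individual clock CpGs, and tests whether composition
shifts, probe chemistry or measurement noise can account for it. The
individual-level datasets such longitudinal designs produce are typically
not shareable, so the package ships a synthetic-data generator that
reproduces the design's statistical structure with known ground truth; every
analysis is exercised against it.

## Epigenetic clocks

A clock is a linear predictor `intercept + Σ_i coef_i · beta_i` over its CpG
panel. Clocks trained on a calibrated age scale use the piecewise
log-linear transform

    f(a) = log(a+1) − log(A+1)      a ≤ A
    f(a) = (a − A) / (A+1)          a > A

with knot `A` ("adult age", default 20 years); ages are read off by the
exact two-branch inverse. Clocks trained directly in years (PhenoAge-style)
use the identity transform. The transform is a per-clock field so users can
encode each published clock faithfully; coefficient files are user-supplied
CSV (`cpg_id, coefficient`, intercept as a reserved `(Intercept)` row, YAML
sidecar for name/transform/knot). Natural logarithms throughout.

Missing clock CpGs are governed by an explicit `missing_policy`: `error`
(default), `mean_impute` (NaN cells filled with the probe's within-dataset
mean; probes absent from the matrix still error, since there is nothing to
average), or `drop` (absent probes contribute zero, with a warning). Real
post-QC datasets rarely retain every published clock CpG, so the policy is
a visible knob rather than a hidden convention.

## Synthetic data generator

The default configuration emulates a dense longitudinal design: 2
individuals × 2 sample types × 24 collection days spanning roughly three
months, 96 samples total. Collection-day gaps are drawn from
{1, 1, 2, 3, 4, 5, 7} days so that some consecutive collections are exactly
one day apart — the pairs the "daily change" index is computed from.

Per probe `p` and sample `s = (individual, sample type, day t)`:

    mu_ps   = Σ_k w_ks · ref_pk                                (cell mixture)
    x_pt    = φ^gap · x_p,t−1 + √(1 − φ^2·gap) · sd_p · ε       (AR(1), logit scale)
    beta_ps = clip( invlogit(logit(mu_ps) + x_pt) + N(0, σ_type), 0, 1 )

* **Cell mixture.** Reference profiles are generated with a stated set of
  discriminating probes on which cell types are spread over an interval of
  width exactly `separation` (default 0.5). The first sample type (PBMC-
  like) mixes all cell types with logistic-normal day-to-day jitter
  (jitter SD 0.3 on the log-weight scale) around a geometric base
  (1/2, 1/4, ...); other sample types are fixed single-cell-type vertices
  (monocyte-like). This is the minimal structure in which composition
  shifts can move apparent methylation in the mixed type but not the
  purified one.
* **Temporal term.** AR(1) on the logit scale is the minimal autocorrelated
  fluctuation model; the logit keeps betas in (0, 1) before measurement
  noise, and the `φ^gap` decay ties autocorrelation to the actual day gap
  while keeping the stationary SD equal to `sd_p` regardless of spacing.
  Default φ = 0.5 per day. Real data do not constrain φ; it is a
  placeholder, not an estimate. Per-CpG stationary SDs follow a lognormal
  prior (median 0.12, log-SD 0.6 on the logit scale), which translates to
  day-to-day beta movements of roughly 0.01–0.05 at mid-range betas.
* **Measurement noise.** Additive Gaussian on the beta scale with a
  design-type-specific SD, default σ_I = 0.01, σ_II = 0.025 — type II
  chemistry is the noisier of the two. Out-of-range values are clipped
  (not resampled); at these noise levels the clipping bias is negligible.
* **Clocks.** Synthetic panels draw coefficients from a user-specified
  distribution. A `coupling` parameter in [0, 1] pairs coefficient
  magnitudes with per-CpG fluctuation SDs through a Gaussian copula at
  correlation −coupling (rank pairing preserves both marginals exactly), so
  generated clocks reproduce the defensive pattern of published clocks:
  large-SD CpGs carry small weights. `center_age` chooses the intercept so
  a flat beta-0.5 profile reads that age, keeping random panels on a human
  scale (defaults: 40 years for the calibrated clocks, 55 for the
  identity-transform clock). Default panel sizes 353 / 391 / 513 CpGs match
  the sizes of the three widely used blood clocks; coefficient scale
  (SD 0.15 on the transformed scale, 4.0 in years for the identity clock)
  puts within-person age SDs at 1–3 years, i.e. ranges of a few years over
  24 time points.

Everything is deterministic given the seed; `SimulationTruth` records the
true mixing weights, per-CpG fluctuation SDs, the AR coefficient, noise SDs
and the noiseless mixture age per sample, so recovery tests can compare
estimates against ground truth.

**What the generator does not emulate:** raw two-channel intensities,
detection-p filtering, SNP-affected or cross-reactive probes, batch/chip
layout effects, annotation–variability coupling (annotations are drawn
independently of SD, so annotation-proportion tests are null by
construction on default simulations), and any real biological covariance
between CpGs beyond shared cell composition. Passing tests therefore
demonstrate that the *machinery* is correct and calibrated, not that real
arrays satisfy the generator's assumptions.

## Normalization

* **raw** — passthrough, labelled `raw`.
* **bmiq** — beta-mixture quantile normalization, per sample. Three-state
  beta mixtures (unmethylated / hemimethylated / methylated) are fitted
  separately to type I and type II probes by EM. The M-step maximizes the
  weighted beta log-likelihood exactly (bounded quasi-Newton on log shape
  parameters; a candidate is accepted only if it improves the objective),
  so the log-likelihood trace is non-decreasing — an asserted invariant.
  Initialization is deterministic: conventional 0.25/0.75 methylation bands
  and empirical quantile bands are both tried and the higher-likelihood fit
  wins; the seed only drives optional random restarts. Betas are clamped to
  [1e−6, 1−1e−6] before likelihood evaluation.

  Type II probes are then quantile-mapped through the *full* fitted mixture
  CDFs, `x' = F_I^{-1}(F_II(x))`. A state-by-state map (outer states via
  their beta CDFs, middle state linear) was evaluated and rejected: the
  three-state fit is not identifiable on strongly bimodal samples, so the
  state indices of two independent fits need not correspond — the
  likelihood can split one methylation mode across two states, and
  state-wise pairing then maps a real mode onto a sliver state. The
  mixture-CDF map depends only on the overall fitted distributions, is
  globally monotone (type II rank order is preserved exactly), and is
  near-identity when the two distributions already agree. Type I probes are
  untouched.
* **gold_standard** — per-sample monotone quantile mapping onto a reference
  beta distribution: each value is replaced by the reference quantile at
  its own rank position, with (r−1)/(n−1) plotting positions so a sample
  already equal to the reference is an exact fixed point. This is a
  documented stand-in for dataset-calibration procedures whose exact
  published details live in inaccessible supplements; the interface
  isolates the choice behind one operation. The pipeline uses the
  dataset-mean probe profile as the default calibration target.

On default simulations the three strategies shift age *levels* but leave
the *degree* of fluctuation essentially unchanged (median range and CV
agree to within a few percent across strategies) — the qualitative
robustness the analysis design anticipates.

## Cell composition

Per-sample proportions solve `min ‖A w − y‖²` subject to `w ≥ 0, Σw = 1`
(SLSQP warm-started from renormalized NNLS) over the 100 probes with the
largest between-reference range (configurable). Reference-based constrained
projection is the field standard for blood arrays; collinear references on
the selected probes trigger an identifiability warning.

Composition-corrected ages are the per-series OLS residuals of age on the
estimated proportions, plus the series mean. The most abundant cell type is
dropped from the design to break the sum-to-one collinearity; zero-variance
regressors are dropped, so constant-composition series pass through
unchanged. Mean add-back keeps ages in years and makes the correction a
pure fluctuation adjustment: the series mean is preserved exactly.

## Fluctuation indices

Per (individual, sample type, clock, normalization, correction) series,
sorted by day:

* **range** = max − min age (years);
* **CV** = sample SD (n−1 denominator) / mean, computed on ages in years;
* **daily change** = max |age difference| over consecutive pairs exactly
  one day apart; flagged undefined when no one-day pair exists. All
  consecutive-pair differences are reported alongside for transparency.

SDs are computed after anchoring each series at its first value, so a
constant series yields exactly 0 (naive one- or two-pass formulas leave
~1e−16 residue, which would break the exact zero-propagation guarantee of
noise-free simulations).

Sample types are compared by classical two-sided paired t-tests, pairing
ages by collection day within each individual; unpaired days are dropped
and counted. Zero-variance difference series are reported, not raised:
t = 0, p = 1 if all differences are exactly zero, t = ±∞, p = 0 otherwise,
both with a degenerate flag — batch runs survive pathological series.

## Clock-CpG characterization

Per-CpG longitudinal SD is computed within each (individual, sample type)
series and averaged across series (configurable: max, or pooled across all
samples). The **contribution** of a clock CpG to age fluctuation is
|coefficient| × SD — the absolute value because ranking by signed products
would conflate direction with magnitude. Quartile groups (top/bottom
floor(n/4), ties broken deterministically by probe id) define
variable/stable CpGs by SD and high/low contributors by contribution.

Group comparisons: Pearson chi-squared (no continuity correction) on the
2 × k annotation contingency tables, with the Bonferroni-adjusted threshold
α / (clocks × sample types) reported alongside (0.05/6 ≈ 0.008 for the
default design) and a low-expected-count flag rather than a silent test
switch; two-sided Wilcoxon–Mann–Whitney on contributions between Infinium I
and II CpGs (exact null for combined n ≤ 20 without ties, normal
approximation with tie correction otherwise); hypergeometric upper-tail set
enrichment over user-supplied term maps with Bonferroni or
Benjamini–Hochberg correction. The coefficient-vs-SD diagnostic reports the
Spearman correlation between |coefficient| and SD; generated clocks with
coupling > 0 reproduce a clearly negative rho through the full pipeline.

## Phenotype association

Simple per-series OLS of epigenetic age on each phenotype item, two-sided
slope test, pairwise deletion of missing values, Bonferroni correction
across all tests in the run (BH available). The series are short,
autocorrelated within-person measurements; repeated-measures structure is
deliberately not modelled, and the output carries a `model` column so the
p-values are read as descriptive. Perfectly collinear or constant inputs
are reported with degenerate conventions (t = ±∞ / p = 0, or t = 0 / p = 1)
rather than raised.

## Numerical conventions

* Betas validated to [0, 1] at container boundaries, with offending
  probe/sample coordinates named in errors.
* EM convergence: relative log-likelihood change ≤ 1e−6, max 100
  iterations.
* Quantile-map inverses evaluated on a 4001-point grid with cumulative-max
  enforcement of monotonicity.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds and parameters give bit-identical outputs, asserted end to end.
* Problem sizes in the test suite and acceptance script (hundreds to a few
  thousand probes, 8–24 time points, 200–1000 Monte-Carlo replicates) are
  chosen so each property is measured with comfortable statistical margin
  while the whole suite runs in minutes.

## Known limitations

* The AR(1) temporal model and its defaults are structural placeholders;
  nothing here estimates the real day-to-day autocorrelation of methylation.
* BMIQ here normalizes within sample against the type I distribution; it
  does not harmonize across samples, and dye-bias, functional normalization
  and noob-style corrections are out of scope.
* The association module's p-values ignore serial correlation; with 24
  autocorrelated time points they are optimistic.
* Deconvolution assumes the supplied references span the true cell types;
  reference-free methods are out of scope.
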