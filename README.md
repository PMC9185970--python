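# epifluct

Short-term epigenetic age fluctuation on longitudinal DNA methylation data.

Epigenetic clocks read an age estimate off a linear combination of
methylation beta values at a fixed CpG panel,

    age = g( intercept + Σ_i coef_i · beta_i ),

where `g` is either the identity or the inverse of the piecewise
log-linear calibration used by first-generation clocks (logarithmic below
an "adult age" knot, linear above it). When the same person is sampled
repeatedly over days to months, the estimated age moves by several years
without any intervention. That background fluctuation matters to anyone
using clocks to judge an intervention at the individual level: an apparent
rejuvenation of 2–3 years is within the range a person can drift in a
week.

epifluct is a tested pipeline for quantifying and dissecting that
fluctuation:

* **clocks** — linear clocks with the calibrated-age transform and its
  exact inverse, explicit missing-CpG policies, CSV round-tripping;
* **normalization** — raw passthrough, per-sample beta-mixture quantile
  normalization of Infinium type II probes onto type I (BMIQ), and
  monotone quantile calibration toward a gold-standard distribution;
* **cell composition** — reference-based deconvolution by constrained
  least squares and mean-preserving composition correction of age series;
* **fluctuation statistics** — per-series range, coefficient of variation,
  maximum one-day change, and paired sample-type t-tests;
* **CpG characterization** — per-CpG longitudinal SD, contribution to age
  fluctuation (|coefficient| × SD), quartile groups, chi-squared
  annotation tests at the Bonferroni-adjusted threshold, Infinium I vs II
  rank-sum tests, hypergeometric set enrichment, and the
  coefficient-vs-SD diagnostic;
* **association** — OLS of ages on blood-test phenotypes with multiplicity
  correction;
* **synthetic data** — a generator reproducing the longitudinal
  two-person, two-sample-type study structure (cell-mixture drift in the
  mixed sample type, AR(1) day-to-day beta fluctuation on the logit scale,
  probe-type-dependent noise, clocks with inverse coefficient–SD coupling)
  with ground-truth tables for recovery tests. Individual-level data from
  real designs of this kind are usually private; the generator is the
  package's test bed and demo substrate.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (`python analysis/01_simulate.py`, then `02`–`06` in order). A
condensed version in the API:

```python
from epifluct import (
    generate_study_design, generate_cell_references, generate_clock,
    generate_longitudinal_betas, compute_epigenetic_age, fluctuation_summary,
)

design = generate_study_design(2, 2, 24, seed=1)          # 96 samples
refs = generate_cell_references(3, 2000, separation=0.5, seed=2)
gen = generate_clock(353, 0.0, ("normal", 0, 0.15), ("horvath", 20.0),
                     coupling=0.8, seed=3, center_age=40.0)
betas, truth = generate_longitudinal_betas(design, gen, refs, seed=4)
ages = compute_epigenetic_age(betas, gen.clock)
print(fluctuation_summary(ages).summary[
    ["individual", "sample_type", "range", "cv", "max_daily_change"]
].round(3).to_string(index=False))
```

Output from `analysis/03_fluctuation.py` on the default simulation
(gold-standard normalization):

```
individual sample_type      clock_name  range    cv  max_daily_change
  person_A        PBMC pan_tissue_like  9.835 0.157             8.260
  person_A    monocyte pan_tissue_like  4.701 0.031             2.491
  person_B        PBMC pan_tissue_like 11.266 0.212             9.808
  person_B    monocyte pan_tissue_like  5.184 0.033             2.478
```

Each row is one person × sample-type series over 24 collections: the
estimated age spans a `range` of several years within three months, the
`cv` is the SD-to-mean ratio of the series, and `max_daily_change` is the
largest age jump between two collections one day apart — here up to ~10
years in the composition-drifting PBMC series versus ~2.5 years in the
purified monocyte series, because the mixed sample type adds cell-mixture
drift on top of per-CpG fluctuation. The same driver prints the median
range/CV per normalization strategy, which agree closely — normalization
moves age levels, not the degree of fluctuation.

The CLI mirrors the library:
`epifluct simulate|normalize|age|deconvolve|correct-age|fluctuate|characterize|associate|run`,
each with `--help`.

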