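# Methods

## The pair-ratio model

A sample's exported Ct values are modeled as

```
Ct[s, m] = mu_m + delta_m * [s is case] + u_s + eps[s, m]
```

with assay baseline `mu_m` (cycles), case-vs-control shift `delta_m`
(cycles; negative = higher expression in cases, since more template lowers
Ct), a per-sample technical offset `u_s` shared by every assay of the
sample, and per-well noise `eps ~ N(0, sigma_m^2)`. Nothing in the pipeline
estimates `u_s`: the pair feature `ΔCt = Ct_b − Ct_a` eliminates it exactly,
which is the entire normalization strategy. Under this model the feature of
pair (a, b) is Gaussian in each cohort with common variance
`sigma_a^2 + sigma_b^2`, so its discrimination has the closed form

```
AUC(a, b) = Phi( |delta_a − delta_b| / sqrt(2 (sigma_a^2 + sigma_b^2)) )
```

which the synthetic generator's truth table tabulates and the test suite
uses as its oracle.

Two orientation conventions coexist and are both recorded on the feature
type: the *working* scale `ΔCt = Ct_b − Ct_a` (rises with a's expression;
all statistics operate here) and the *reported* ratio `2^(Ct_a − Ct_b)`,
the conventional printed form for a pair labeled "a/b". On the reported
scale the exponent runs opposite to expression; treating it as anything but
output formatting leads directly to the raw-ratio degeneracy described
below.

## Ct parsing and censoring

Wells that never amplify within the instrument limit ("Undetermined", "NA",
empty) are imputed at `max_cycles` (default 40, the standard cycle count)
and flagged censored rather than dropped: dropping would silently change
sample counts per pair, and detectability is a QC decision, not a parsing
one. Replicate wells for one (sample, assay) collapse by median — robust to
single-well dropouts; the upstream protocol does not specify an
aggregation. Assay names are harmonized via a packaged synonym table
(miRBase naming drifts, e.g. `miR-451a` vs `miR-451a-5p`) with `hsa-`
prefixes stripped.

## QC thresholds

The elimination stage drops assays with poor detectability, excess
variability, or failed run controls. The numeric thresholds are package
conventions, chosen once and echoed into every report:

| parameter | default | units | rationale |
|---|---|---|---|
| `min_detect_rate` | 0.8 | fraction, per cohort | an assay censored in >20% of either cohort contributes mostly imputed values |
| `max_assay_sd` | 3.0 | Ct cycles, per cohort | 3 cycles ≈ 8-fold spread; beyond that a plasma assay is dominated by technical noise |
| `ntc_max_ct_margin` | 5.0 | cycles | an NTC within 5 cycles of the sample median indicates contamination above trace level |
| `spikein_sd_max` | 2.0 | cycles across plates | spike-in drift beyond 2 cycles marks an extraction/RT batch problem |

Spike-ins are flags only, never normalizers — normalization is the ratio
design's job, and mixing the two would reintroduce plate dependence.

## Single-pair evaluation

AUC is computed from midranks (equal to the Mann–Whitney U statistic over
`n1*n0`, ties counted half) — exact, O(n log n), and invariant under
monotone transforms, so log2 features and fold-ratios give identical
screening results. Pairs are oriented so AUC ≥ 0.5, with the flip recorded.
The confidence interval defaults to DeLong's placement-variance method
(truncated to [0, 1]; zero-variance cases — e.g. perfect separation — are
flagged degenerate); a stratified percentile bootstrap (2000 resamples,
seeded) is available. The Mann–Whitney test uses the exact null when
`n1*n0 <= 400` and the data are tie-free, else the tie-corrected normal
approximation.

The logistic fit is a univariate maximum-likelihood fit on the oriented
log2 feature. Classification metrics are read in-sample at probability 0.5,
with p = 0.5 itself classified as case. Perfect separation (where the MLE
diverges) falls back to a deterministic midpoint step rule, flagged
`separable`; an exhaustive screen over a thousand pairs will hit such cases
routinely, and a divergent fit would otherwise poison the results table. A
constant feature yields the flagged degenerate result (AUC 0.5, slope 0).

Evaluation is deliberately in-sample: the screening design fits and scores
on the same cohort, and the pipeline mirrors that, so its outputs are
discovery-phase numbers. A cross-validation mode is intentionally absent
from the default path rather than half-supported. No multiple-testing
correction gates the screen; a Benjamini–Hochberg column is present in the
output for reference only.

## Combination classifiers

The combination score is an unweighted mean of member features pushed
through a sigmoid, thresholded at p = 0.5. In the default
`standardized_log` mode each member's oriented log2 feature is centered at
the midpoint between its class means and scaled to unit pooled within-class
SD before averaging — the minimal preprocessing that makes score 0 coincide
with the decision boundary so the p = 0.5 rule is meaningful, while keeping
the combination strictly equal-weight.

The alternative `raw_ratio` mode implements the literal printed convention:
the mean of the positive `2^(Ct_a − Ct_b)` ratios through the sigmoid. All
ratios are positive, so every score is positive, every probability exceeds
0.5, and every sample is classified as a case (specificity 0). The mode
ships, flagged with a caveat in code, logs, and reports, purely to document
this internal inconsistency of the ratio-through-sigmoid formulation; a
regression test asserts the degeneracy.

The search evaluates **all** C(n_gated, k) combinations (k configurable
1–4, default 3) with vectorized rank statistics in chunks — no greedy or
heuristic shortcut — and ranks survivors by AUC, then accuracy, then
lexicographic member ids (the tie-break is this package's choice). The
post-search acceptance criteria (`min_sens`, `min_spec`, `min_auc`) default
to no filtering and are fully exposed in configuration, since no principled
default exists. The search has no randomness; identical inputs give
byte-identical rankings regardless of input order.

## Plasma/tissue concordance

Profile similarity between plasma and matched tumor tissue is quantified as
Spearman and Pearson correlations of the two per-assay mean Ct vectors
(uncensored wells only; at least 3 jointly detected assays required),
alongside the mean Ct shift (tissue − plasma; typically negative, as tissue
yields more template) and a detectability cross-table. Correlation of mean
profiles is this package's choice of statistic for a claim usually made by
eye from overlaid profile plots, and outputs label it as such.

## Synthetic data: what it does and does not emulate

Defaults are the targeted study conditions: 30 cases vs 30 controls, 48
assays (the packaged panel's identifiers), baselines `mu ~ U[22, 34]`
cycles, per-assay SD 1.0, sample-offset SD 1.5, censoring at 40 cycles,
four samples per plate with pass-by-default control wells (UniSp3 ≈ 20,
UniSp6 ≈ 21, positive oligo ≈ 24, BlankSpot/NTC censored); switches inject
NTC contamination and spike-in drift for QC tests. A 61-assay variant with
13 "killed" assays (baseline 41, one cycle above the ceiling, giving a
detect rate around Φ(−1) ≈ 0.16) reproduces the 61 → 48 elimination
scenario. Matched tissue profiles are the plasma per-assay means plus a
global shift (default −6 cycles) and per-assay pattern noise shared across
the (default 3) tissue samples, so the induced profile correlation is
`s/√(s² + η²)` for profile SD `s` and noise SD `η` — analytically checkable.

The Gaussian/additive structure is the *minimal* model under which ratio
normalization is exactly correct. Real plasma qPCR additionally shows
amplification-efficiency differences between assays, correlated and
heavier-tailed noise, hemolysis artifacts, and demographic covariates —
none of which the generator emulates. Passing recovery tests therefore
demonstrates that the pipeline implements its statistics correctly under
its own assumptions, not that those assumptions hold in patient data.

One structural consequence worth naming: planting a shift on *any* assay
makes every pair containing that assay genuinely differential (separation
`|delta_a − delta_b|`). "Plant five disjoint pairs" therefore yields five
designated pairs at the target AUC plus collateral differential pairs
(opposite-sign members across pairs at full separation, planted-vs-null at
half). Recovery tests consequently assert against the truth table's full
differential set, not against the designated five alone — a scenario with
exactly five differential pairs and 1123 exact nulls does not exist in an
additive per-assay model.

## Numerical choices

- Midrank AUC and the U statistic are computed from one shared ranking;
  their identity is asserted to 1e−12 rather than assumed.
- Null p-value uniformity is checked on p-values from disjoint pairs across
  independent replicate datasets. Within one dataset the 1128 pair features
  are strongly cross-correlated (two pairs sharing an assay have feature
  correlation ±0.5; each pair shares an assay with 92 others), which
  inflates the dispersion of an empirical CDF far beyond the iid assumption
  of a Kolmogorov–Smirnov test; applying KS to one dataset's 1128 dependent
  p-values would reject a correct implementation most of the time. The mean
  AUC over all 1128 pairs of one null dataset *is* checked directly
  (0.5 ± 0.02), since averaging is robust to that dependence.
- Probability exactly 0.5 classifies as case, everywhere (single pairs and
  combinations).
- Seeds are mandatory in the generator config; identical configurations
  produce bit-identical files. Bootstrap and pipeline runs thread a single
  integer seed.
- Degenerate inputs: constant features are flagged, not errored;
  single-class label vectors are errors; a QC report that would eliminate
  every assay is an error.

## Problem sizes

The test suite and acceptance script run at the pipeline's natural scale —
60-sample cohorts, 1128-pair screens, the full C(76,3) = 70,300-combination
search — plus 200-replicate AUC recovery, 47-replicate uniformity, and
500-replicate DeLong coverage simulations; the whole suite completes in
well under a minute on one core. Convergence of empirical to theoretical
pair AUC is additionally checked at n = 500 + 500.

## Known limitations

- In-sample metrics only by default; no covariate adjustment (age/sex) and
  no survival endpoints.
- No inter-plate Ct calibration (by design — the ratio features make it
  unnecessary under the additive model, and only under it).
- The generator's independence and normality assumptions understate
  real-world false-discovery behaviour of a 1128-pair screen with no
  multiplicity control.
- Triplet or higher-order ratio features are out of scope.
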