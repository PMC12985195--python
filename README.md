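# mirpair

Pairwise Ct-ratio miRNA biomarker discovery for two-cohort RT-qPCR panels.

## The problem

Circulating microRNAs are promising liquid-biopsy analytes: they are stable
in plasma, cheap to assay by RT-qPCR, and a panel of a few dozen targets can
capture both tumor-promoting (oncomiR) and tumor-suppressive signals. The
catch is normalization — plasma qPCR has no trusted housekeeping gene, and
per-sample technical effects (RNA input, extraction efficiency, plate
offsets) shift every Ct value in a sample by roughly the same constant.

`mirpair` implements the pair-ratio answer to that problem as a tested,
reusable pipeline. For every unordered pair of panel assays (a, b) it forms
the within-sample feature

```
ΔCt = Ct_b − Ct_a            (log2 scale; rises with a's expression)
Ratio = 2^(Ct_a − Ct_b)      (reported fold-ratio scale)
```

Any per-sample additive Ct offset cancels *exactly* in the difference, so
each pair is a self-normalized candidate biomarker. The pipeline then:

1. **QC-filters** assays (detectability and variability per cohort;
   spike-in / NTC run controls as flags, never for normalization);
2. **screens** all n(n−1)/2 pairs as single-feature logistic classifiers —
   sensitivity/specificity/accuracy at p = 0.5, midrank AUC with a DeLong
   (or bootstrap) 95% CI, and a two-sided Mann–Whitney test, exploiting the
   identity AUC = U/(n₁n₀);
3. **gates** pairs at AUC ≥ 0.8 (inclusive; no multiple-testing
   adjustment — this is a discovery screen);
4. **exhaustively searches** all C(n_gated, k) equal-weight k-pair
   combination classifiers (default k = 3), scoring
   `P(case) = 1/(1 + e^(−score))` with `score` the unweighted mean of the
   standardized oriented pair features, thresholded at p = 0.5.

A seeded synthetic-data module generates two-cohort qPCR datasets with the
exact statistical structure the design assumes — per-sample offsets,
per-assay group shifts, Ct-40 censoring, control wells, matched tissue
profiles — plus a ground-truth table with the closed-form pair AUC
`Φ(|δ_a − δ_b| / √(2(σ_a² + σ_b²)))`, so every stage is testable without
patient data. The packaged default panel is a 48-assay glioblastoma plasma
panel with role and brain-enrichment annotations.

## Worked example

Generate a 30 + 30 cohort with one planted pair (miR-17-5p up, miR-19b-3p
down in cases, 3.3 cycles apart → theoretical pair AUC 0.95), run the full
pipeline, and render the report:

```bash
mirpair simulate --seed 11 --out demo/data \
    --plant "miR-17-5p=1.65" --plant "miR-19b-3p=-1.65"
mirpair run --ct demo/data/ct_long.csv --out demo/run --seed 11 --auc-min 0.8
mirpair report --bundle demo/run
```

The report prints (abridged):

```
## Top 5 pairs
- miR-17-5p/miR-19b-3p: AUC 0.943 (95% CI 0.892-0.994), sens 0.83, spec 0.87, acc 0.85, Mann-Whitney p 3.82e-09
- miR-16-5p/miR-19b-3p: AUC 0.929 (95% CI 0.864-0.994), sens 0.83, spec 0.87, acc 0.85, Mann-Whitney p 1.20e-08
...
## Top 6 combination classifiers
- miR-16-5p/miR-19b-3p + miR-17-5p/miR-18a-5p + miR-19b-3p/miR-26a-5p: AUC 0.984, sens 0.90, spec 0.97, acc 0.93
...
## Log
single_pair_eval: 51 pairs passed the AUC >= 0.8 gate
combo_search: 20825 combinations of k=3 evaluated
```

Reading this: the planted pair tops the screen at AUC 0.943, close to its
theoretical 0.95. Pairs such as miR-16-5p/miR-19b-3p score high too — any
pair containing a shifted assay is genuinely differential under the additive
model, which is why 51 pairs clear the gate from a single planted effect.
Combining three pairs lifts the in-sample AUC to 0.984. All metrics are
in-sample by design (discovery mode); they are optimistic estimates, not
validated performance.

The same stages are available as library calls (`generate_cohort`,
`assess_assays`, `evaluate_all_pairs`, `select_pairs`,
`exhaustive_combo_search`, `profile_concordance`) returning plain
dataframes and dataclasses.

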