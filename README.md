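# actimood

Variability, complexity and similarity-graph analysis of wrist-actigraphy
recordings, built for paired within-subject comparison of mood states in
bipolar disorder (mania vs euthymia).

Motor activity is a core symptom domain of bipolar mood episodes: the manic
state shows *reduced relative variability* but *increased complexity* of
minute-to-minute activity compared with the same person in remission.
`actimood` implements the full analysis chain needed to quantify this:

1. **Preprocessing** — raw 32 Hz tri-axial acceleration (g-equivalents) is
   collapsed to per-minute activity counts, `count[m] = mean |√(x²+y²+z²) −
   gravity|` over the minute's 1920 samples; recordings with < 5% missing
   minutes are mean-imputed, others rejected; analysis epochs (the full
   1190-minute window, 120-minute morning/evening windows) are extracted.
2. **Variability** — mean, CV% (= 100·SD/mean), RMSSD% (= 100·RMSSD/mean),
   the RMSSD/SD ratio, and lag-1 autocorrelation.
3. **Complexity** — sample entropy SampEn(m = 2, r = 0.2·SD) and a
   symbolic-dynamics statistic: the series is coarse-grained to 6 symbols
   (equal-width bins after clipping to mean ± 3 SD) and the number of
   distinct overlapping 3-symbol words (out of 6³ = 216) is counted.
4. **Similarity graph** — each time point becomes a node; nodes u, v are
   joined iff |u − v| < k and max(x_u, x_v)/min(x_u, x_v) < 1.2. Six
   summaries are computed per k: mean edges per node (2E/n), connected
   components, bridges, missing edges between direct neighbours, isolated
   time points, and 3-cliques.
5. **Cohort statistics** — paired-samples t-tests (Wilcoxon signed-rank for
   3-cliques) between states, Bonferroni correction for the within-state
   morning-vs-evening family (0.05/4 = 0.0125), and a Pearson correlation
   matrix across features.
6. **Synthetic cohorts** — a seeded generator of paired manic/euthymic
   recordings (gated circadian + ultradian sinusoids × autocorrelated
   log-normal noise × burst/drop events) so the entire pipeline is testable
   without patient data.

The per-series feature stages are exposed both as plain functions and as
scikit-learn transformers (`VariabilityExtractor`, `ComplexityExtractor`,
`SimilarityGraphExtractor`, `ActigraphyFeatureExtractor`) that compose with
sklearn pipelines.

## Worked example

```python
from dataclasses import replace
from actimood import extract_features, simulate_recording
from actimood.simulate import euthymic_preset

rec = simulate_recording(replace(euthymic_preset().params, seed=7))
row = extract_features(rec, ks=(2, 5))
for k in ("mean", "cv_percent", "rmssd_sd_ratio", "sample_entropy",
          "symbolic_count", "mean_edges_k2", "bridges_k5", "triangles_k5"):
    print(f"{k:>16} = {row[k]:.3f}")
```

```
            mean = 185.724
      cv_percent = 118.094
  rmssd_sd_ratio = 0.619
  sample_entropy = 0.091
  symbolic_count = 59.000
   mean_edges_k2 = 1.198
      bridges_k5 = 140.000
    triangles_k5 = 1482.000
```

A euthymic-preset recording has a high relative SD (the deep sleep/wake
swing dominates), low sample entropy (smooth, predictable dynamics; note
that a large SD also widens the SampEn tolerance r), and a dense similarity
graph (many consecutive minutes within 20% of each other, hence ~1.2 edges
per node at k = 2 and many 3-cliques at k = 5).

A full paired cohort analysis:

```python
from actimood import simulate_cohort, cohort_feature_table, state_comparison_report

recs = simulate_cohort(14, seed=1)          # 14 subjects x {manic, euthymic}
table = cohort_feature_table(recs)          # one row per (subject, state, epoch)
report = state_comparison_report(table, epoch="full-1190")
```

which for the six headline features prints (mean per state, paired p):

```
       feature  mean_manic  mean_euthymic  p_value  significant
    cv_percent     102.085        112.505    0.011         True
rmssd_sd_ratio       0.838          0.446    0.000         True
sample_entropy       0.558          0.099    0.000         True
 mean_edges_k2       0.761          1.139    0.000         True
    bridges_k5     302.000        186.071    0.000         True
  triangles_k5     592.929       1299.929    0.001         True
```

— the injected manic signature: relative SD down, RMSSD/SD up, sample
entropy up, fewer k = 2 edges, more k = 5 bridges, fewer 3-cliques.

The same pipeline is available from the shell:

```sh
actimood simulate --out cohort/ --n-pairs 14 --seed 7
actimood extract  --manifest cohort/manifest.csv --out features.csv
actimood compare  --features features.csv --out-dir report/
actimood figure1-check       # the 11-point worked example below
```

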