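# Methods

## From raw acceleration to activity counts

The raw signal is tri-axial acceleration in gravitational-force equivalents
(g) at 32 Hz, as produced by wrist-worn research devices.  The per-minute
activity count is the mean absolute deviation of the acceleration magnitude
from gravity over the minute's 32 × 60 = 1920 samples:

    count[m] = (1/1920) * sum over minute m of | sqrt(x² + y² + z²) − gravity |

The gravity constant defaults to 1.0 and is configurable: devices that emit
raw integer units (e.g. 1/64 g steps) can be handled by scaling on input —
the pipeline is agnostic to the count unit, and every relative feature
downstream (CV%, RMSSD%, ratio, autocorrelation, SampEn, symbolic count,
all graph metrics) is invariant to positive rescaling of the counts, which
the test suite asserts.

A trailing partial minute is discarded, not padded.  Missingness is defined
at the minute level: a recording is analysable when strictly less than 5% of
its minutes are missing, in which case each missing minute is replaced by
the arithmetic mean of the observed minutes (this preserves the observed
mean exactly); at or above 5% the recording is rejected with the offending
fraction attached to the error.

Analysis epochs: the full epoch is the first 1190 minutes of the recording
(recordings must share a length for graph metrics to be comparable, and
1190 is the shortest admissible recording length in the study design this
package follows).  Morning and evening epochs are 120 minutes placed at
fixed clock windows, defaulting to 08:00–10:00 and 20:00–22:00.  Post-hoc
visual window selection is deliberately replaced by explicit, reproducible
`EpochSpec`s; windows that do not fit inside a recording are skipped with a
warning.

## Variability features

For a fully observed epoch x₁…xₙ:

- mean: arithmetic mean;
- CV% = 100 · SD/mean with the sample SD (n − 1 denominator).  Activity
  series have unstable means, so dispersion is reported relative to the
  mean throughout;
- RMSSD% = 100 · sqrt( Σ (x_{t+1} − x_t)² / (n − 1) ) / mean (n − 1
  successive differences, n − 1 denominator);
- RMSSD/SD: the ratio of the raw quantities; equal to RMSSD%/CV% up to
  rounding, which is asserted as an invariant;
- lag-1 autocorrelation: Σ (x_t − x̄)(x_{t+1} − x̄) / Σ (x_t − x̄)², the
  standard single-mean acf estimator, bounded in [−1, 1].

Degenerate inputs are flagged, never silently zeroed: a zero mean makes
CV%/RMSSD% NaN, a zero SD makes the ratio and the autocorrelation NaN.

## Complexity features

**Sample entropy** follows the Richman–Moorman convention: template length
m = 2, tolerance r = 0.2 × sample SD, Chebyshev distance, matches counted
as ordered pairs of distinct template start positions with distance ≤ r,
self-matches excluded, and both the length-m count B and the length-(m+1)
count A taken over the same n − m start positions so that A/B is a proper
conditional probability; SampEn = −ln(A/B).  Because r scales with the SD,
SampEn is exactly invariant under positive affine maps of the series.  A
zero-variance series (r = 0) and a vanishing A or B are flagged NaN with a
warning naming the cause.  The implementation is vectorised over the full
distance matrix (O(n²) memory, ~11 MB at n = 1190); tests compare it to an
independent loop-based counting oracle at 1e-12.

**Symbolic dynamics**: values are clipped to mean ± 3 SD (outlier taming),
the clipped range is split into 6 equal-width bins — left-closed, the top
bin right-closed, with bin edges derived from the clipped minimum/maximum
rather than from mean ± 3 SD directly, so the alphabet always spans the
observed range — and the statistic is the number of distinct overlapping
3-symbol words, between 1 and 6³ = 216.  A zero-width range degenerates to
the single word "111" (count 1).  The distinct-word-count reading of the
statistic matches the magnitudes reported for this family of analyses
(~115–130 of 216 over 1190 minutes, ~41–50 over 120 minutes) and is
recorded here as an interpretation, not an externally fixed definition.

## The similarity graph

Nodes are time points 1…n with weights x_u.  Nodes u, v are adjacent iff

    comparator(|u − v|, k)   and   max(x_u, x_v) / min(x_u, x_v) < 1.2 .

The 20% similarity band mirrors the r = 0.2·SD tolerance of SampEn but is
ratio-based and therefore scale-free.  Two details of the published
definition are ambiguous and are fixed here explicitly:

- **Distance comparator.** The default is strict, |u − v| < k, because only
  the strict reading reproduces the published 11-point worked example
  exactly (13 edges; a ≤ k reading adds the two distance-5 pairs and gives
  15).  A `less_equal` variant is provided because published k = 2 mean
  edge counts (up to 2.23) exceed the strict-comparator ceiling of 2·(n−1)/n
  < 2; the two conventions are never mixed silently.  A corollary of the
  strict default: k = 2 graphs contain only distance-1 edges, so k = 2
  triangle counts are structurally zero; triangle contrasts are evaluated
  at k = 5.
- **Zero counts.** max/min is undefined at zero.  The default treats
  (0, 0) as similar (ratio → 1 by continuity) and (0, positive) as
  dissimilar; an `any_zero_dissimilar` rule is available.

Ratios at the threshold boundary (e.g. 6/5 vs 1.2) resolve exactly in IEEE
arithmetic for small integer series, which the worked example exercises
(edge 8–9 absent).

The six metrics: edge total E and mean edges per node 2E/n; connected
components (scipy union-find); bridges by a single-pass iterative Tarjan
lowpoint algorithm (valid because the construction yields a simple graph);
missing direct edges = (n − 1) minus the number of distance-1 edges — by
definition independent of k, since distance-1 pairs are admitted for every
k ≥ 2 (published tables show small k-dependent differences in this column;
the literal definition is followed here and the mismatch documented rather
than reverse-engineered); isolated nodes = degree-0 count; triangles via
the sparse-matrix identity tr(A³)/6, each 3-clique counted once.  All four
nontrivial metrics are oracle-checked against brute-force loop
implementations and against networkx on hundreds of random instances.

## Paired statistics

State contrasts are paired within subject: paired-samples t-test (n − 1
df, two-sided) for every feature except 3-cliques, whose skewed counts are
tested with the related-samples Wilcoxon signed-rank test (zero differences
dropped; exact null when the absolute differences are tie-free and the
sample is small, normal approximation with midranks otherwise — scipy's
`wilcoxon` with `zero_method="wilcox"`).  Degenerate contrasts
(zero-variance differences, all-zero differences) raise a typed error and
are flagged in reports instead of producing a fabricated p.

Significance in state-vs-state tables is assessed at uncorrected α = 0.05;
the Bonferroni correction applies to the within-state morning-vs-evening
family of four tests, giving the 0.05/4 = 0.0125 threshold.  Feature
inter-relations are summarised by a Pearson correlation matrix with
two-sided p-values from the t transform with n − 2 df; zero-variance
features are flagged as undefined columns.

## The synthetic cohort generator

The generator is phenomenological — it emulates the statistical signature
of per-minute actigraphy, not the physiology behind it:

    counts[t] = gate(t) · max(0, mesor + A_c sin(2πt/1440 + φ)
                                       + A_u sin(2πt/240 + ψ)) · noise(t) · event(t)

- `gate` drops activity to `sleep_level` inside a nightly sleep window
  (circadian trough centred in the window);
- the 240-minute sinusoid models the ~4-h ultradian rest-activity
  oscillation, with a random phase per recording;
- `noise` is unit-mean log-normal with stationary coefficient of variation
  `noise_dispersion` and AR(1) persistence `noise_smoothness` on the log
  scale.  The persistence term is essential: minute-to-minute human
  activity is sticky (lag-1 autocorrelation ≈ 0.7–0.9), and without it the
  similarity graph of generated data is far sparser than that of real
  recordings and the bridge/triangle contrasts invert;
- rare `event` factors (probability `irregularity` per minute; 50/50
  bursts ×3–6 or drops ×0–0.15) inject the bursts real traces show.

All draws come from one `numpy` PCG64 generator per recording in a fixed
order (ultradian phase, noise innovations, event positions, types,
factors), so output is bit-reproducible from the seed across platforms.

Mood-state presets (defaults, counts/min): euthymic — mesor 320, circadian
amplitude 185, ultradian amplitude 60, sleep 23:00 + 450 min at level 0.05,
dispersion 0.55, smoothness 0.90, irregularity 0.004; manic — mesor 340,
circadian amplitude 70, ultradian amplitude 80, sleep 300 min at level
0.35, dispersion 0.70, smoothness 0.85, irregularity 0.025.  The manic
preset encodes the attenuated-circadian-cycle account of mania: a
shallower, shorter sleep gate and smaller 24-h amplitude lower the relative
SD; the smaller SD shrinks the SampEn tolerance r while dispersion and
burstiness rise, so sample entropy increases; rougher consecutive ratios
thin the similarity graph (fewer edges and 3-cliques) and leave more
bridges.  With these defaults a 14-pair cohort lands near the magnitudes
reported for real patients (euthymic mean ≈ 240 counts/min, CV ≈ 112%;
manic mean ≈ 285, CV ≈ 101%) without claiming to reproduce them.

Cohorts add subject-level random effects shared across the two states of a
subject (log-normal multipliers on mesor and amplitudes, σ = 0.12/0.15; a
normal ±30 min shift of the sleep window), so paired contrasts isolate the
state effect.

`simulate_raw` inverts preprocessing for end-to-end tests: each minute's
target count c is expanded into 1920 samples with magnitudes 1 + c·e where
the non-negative factors e are rescaled to unit block mean, pointing in
uniformly random directions — the per-minute mean of |magnitude − 1|
equals c to float rounding, so `minute_counts` recovers the target.

### What the generator does and does not show

Passing the directional-recovery test shows that the *pipeline* correctly
detects the injected manic signature (relative SD ↓, RMSSD/SD ↑, SampEn ↑,
k = 2 edges ↓, k = 5 bridges ↑, k = 5 3-cliques ↓) from data with realistic
marginal and short-range structure.  It does not validate the generator as
a model of bipolar actigraphy: real recordings have behavioural structure
(meals, commutes, medication times), non-stationary noise, device artefacts
and missingness patterns the generator does not emulate, and absolute
feature magnitudes (notably SampEn and RMSSD%) differ from patient values.

## Problem sizes and numerical choices

- Sample-entropy oracle comparisons run at n = 80–150 (the O(n²) loop
  oracle), the vectorised implementation at the full n = 1190.
- Graph oracle equivalence uses 200 random series of length ≤ 200 with
  k ∈ [2, 8), alternating both distance comparators, zeros injected to
  exercise the zero-pair rule.
- Directional recovery uses 30-pair cohorts over 20 seeds at the default
  1190-minute length and requires the full sign pattern in ≥ 90% of seeds.
- Null calibration draws both states from the euthymic preset at 120
  minutes, 14 pairs, 1000 replicates, and requires the paired-t rejection
  rate on CV% to sit in 0.05 ± 0.02.
- Ties and thresholds: the similarity criterion is strict (<) on both the
  ratio and the default distance comparison; symbol-bin edges are
  left-closed with the top bin right-closed; SampEn matching is ≤ r.

## Known limitations

- The morning/evening windows are fixed clock windows; per-subject
  chronotype adaptation (which the post-hoc visual procedure this replaces
  effectively did) is out of scope.
- The Wilcoxon exact null is unavailable under ties (midrank normal
  approximation is used instead), which can matter at very small n with
  heavily tied counts.
- Graph metrics assume equal-length epochs across recordings; comparing
  counts (components, bridges, triangles) across different lengths is not
  meaningful and is not prevented beyond the epoch machinery.
- The k = 2 similarity graph under the strict comparator cannot contain
  triangles; analyses wanting k = 2 clique structure must use the
  `less_equal` comparator explicitly.
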