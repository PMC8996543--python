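# Methods notes

## Scope and assumptions

`actconn` analyzes extracted ROI × time signal matrices; it assumes ROI
identification, motion/drift correction, ΔF/F computation (calcium) and
volume preprocessing (BOLD) happened upstream. Signals are treated as
stationary over the recording; the Pearson correlation is the connectivity
measure throughout, so only linear, zero-lag dependence is captured.
Degrees — counts of suprathreshold correlation partners — are the only
graph statistic used; no partial correlations, Fisher transforms, or
higher-order graph metrics.

## Activity

The primary metric is the population variance of each ROI's series
(divisor *T*, matching the definition *ac_i* = mean((*s_i* − mean)²)
exactly rather than the unbiased *T*−1 convention; at *T* ≈ 10³ the
difference is negligible, but the printed definition is the contract).
Variance is computed on raw series; optional z-normalization
(`normalize=True`) standardizes each row *before* analysis and therefore
equalizes all variance activities — it is off by default and only
meaningful with the event-integral metric.

The event-integral metric integrates signal above a per-ROI baseline,
μ_i, estimated as the mean of the samples at or below the row's
*q*-quantile (default *q* = 0.5). This replaces Bayesian peak/background
inference with a declared, testable rule. Two properties matter: for a
trace that is mostly baseline with sparse positive events the estimate is
insensitive to the events; and for symmetric noise of scale σ it is biased
low by ≈ 0.80σ (the sub-median truncated mean), which cancels in
comparisons across ROIs with similar noise. A constant row returns that
constant. Silent-ROI filtering (`filter_silent_rois`) is available but off
by default; ties at the cutoff quantile are retained.

## Threshold selection

The τ grid defaults to 0.05…0.95 in steps of 0.05 — spanning the optima
typically reported for calcium (0.4–0.6) and BOLD (≈0.7) data — and the
comparison is strict (ρ > τ), so a correlation exactly at τ never forms an
edge and negative correlations never connect. At each τ the degree
distribution is fitted on the log₁₀–log₁₀ scale by OLS; *r²* is invariant
to the logarithm base, the exponent estimate γ̂ (negated slope) is not and
is reported in base 10. Bins require *k* ≥ 1 and *P(k)* > 0 (the log of a
zero-degree bin is undefined); fits with fewer than 3 usable bins are
undefined (NaN in the scan) rather than errors. Ties in the argmax go to
the smallest τ (the more conservative, denser network). Because any
two-parameter line fits two points, and a flat distribution is fitted
exactly by a flat line, an *r²* near 1 with γ̂ ≤ 0 is flagged with a
warning rather than trusted silently.

## Exact 1-D k-means

Level classification uses the fact that optimal 1-D k-means clusters are
contiguous in sorted order: dynamic programming over split points
(O(k·n²) with prefix sums) returns the global minimum within-cluster sum
of squares deterministically, removing the seed dependence of Lloyd-style
iterations. Clusters are numbered by descending centroid (level 1 =
high). Degenerate inputs with fewer distinct values than *k* reduce *k*
and record it; runs of identical values straddling an optimal boundary
are moved wholly to the side with lower total cost, remaining exact ties
toward the higher level. *k* = 3 by default; *k* = 5 is supported.

## Population statistics

Joint (AL, CL) tables are exact cross-tabulations; their marginals equal
the per-measure level fractions by construction. Cohort uncertainty uses
the percentile bootstrap — subjects resampled with replacement, tables
averaged per iteration, elementwise 2.5/97.5 percentiles — with 25
iterations for tables and 7 for curves as defaults. Both counts are
deliberately small defaults kept for comparability; they are configurable,
and a note is logged below 100 iterations since percentile bands are
coarse there. Activity-sorted degree curves are smoothed with LOWESS
(tricube weights, span `frac = 0.3` of the points, 0 robustifying
iterations); with fewer than 10 ROIs smoothing is skipped. Cross-subject
curve bands interpolate each smoothed curve onto 101 evenly spaced
normalized ranks.

## Null models

The shuffle applies one uniform permutation to the flattened R×T matrix,
destroying temporal structure everywhere (a per-row mode that preserves
row marginals exists behind a flag). Additive noise is iid Normal(0, s)
with sweep defaults s ∈ {0.1, 0.5, 1.0, 2.0}; correlations attenuate as
ρ/(1 + s²/σ²). Simulated cohorts draw a random correlation matrix
C = normalize(A·Aᵀ/n + jitter·I) (unit diagonal; jitter 0.05 keeps the
spectrum away from zero and is raised once tenfold on a factorization
failure) and set S = L·X with L the Cholesky factor, X iid standard
normal, so rows of S have population correlation C. All generators are
deterministic given their seeds.

## Synthetic cohorts

The generator emulates the statistical contrast the analysis is designed
to detect, with three archetypes per subject (defaults: 20 hub, 20
active, 160 background ROIs; 1800 frames; 9 subjects):

- **hubs** share a white Gaussian latent scaled to `hub_amp = 0.3`
  (unit-free signal sd), plus independent residual noise sized so the
  pairwise hub correlation equals `hub_latent_corr = 0.8` after
  observation noise. The latent is kept white deliberately: an
  autocorrelated latent would inflate spurious hub–active sample
  correlations and blur the archetype contrast that makes the recovery
  experiment interpretable.
- **active** ROIs fire independent Poisson event trains
  (`active_event_rate = 0.05` events/s, amplitude 3.0 with lognormal
  jitter σ = 0.25). Calcium events are convolved with an
  exp(−t/1.8 s) indicator-decay kernel at dt = 0.5 s (≈2 Hz volumes);
  BOLD subjects are band-pass filtered to 0.008–0.09 Hz at dt = 2 s
  (order-8 Butterworth, applied after observation noise as in fMRI
  preprocessing, keeping ≥95% of each trace's tapered-periodogram power
  in band).
- **background** ROIs are observation noise only
  (`obs_noise_sd = 0.1` everywhere).

Per-subject seeds are root seed + subject index, so cohorts are
byte-reproducible.

What the generator does **not** emulate — and hence what recovery tests
do and do not show: there is no spatial geometry, no hemodynamic forward
model beyond band-limiting, no photobleaching or motion artifacts, no
graded continuum of archetypes, and real recordings have orders of
magnitude more ROIs with broad, heterogeneous correlation structure.
Passing recovery tests demonstrates that the pipeline detects the
designed contrast; it is not evidence about real brains.

## Known limitations

Two desk-scale behaviors of the synthetic benchmark are worth flagging.

First, temporally smooth signals inflate the null distribution of sample
correlations: with the default calcium kernel the pairwise null sd among
active ROIs is ≈0.045 versus ≈0.024 for white rows at *T* = 1800. At low
thresholds active ROIs therefore carry more chance edges than background
ROIs, and because the 20 hubs rank directly below the actives in
activity, the LOWESS span (0.3) smears their high-degree bump into the
top of the rank grid. The bootstrapped mean curve on generator-default
cohorts consequently sits *higher* at the high-activity tail than at the
low-activity tail — the opposite of what the same pipeline shows on real
recordings, where high-degree ROIs sit low in the activity ranking. The
archetype-level recovery (exclusivity 0; hubs in CL‑1∪2 and never AL‑1;
actives in AL‑1∪2 and never CL‑1) is unaffected.

Second, small shuffled cohorts are not a clean negative control for the
power-law fit: the shuffled marginal is heavy-tailed (it contains the
calcium transients), so at τ = 0.10 a sparse, geometric-like degree
distribution over k = 1…4 arises whose short log–log range is nearly
straight — *r²* ≈ 0.92 with only 3–5 usable bins. At 200 ROIs a few-bin
fit can score highly without any scale-free structure; the minimum-bin
guard (3) removes only the most degenerate cases. The complementary
shuffle result is exact, however: at τ = 0.4 shuffled data retain zero
suprathreshold connections regardless of the original activity.

## Problem sizes

The bundled tests and the acceptance script run the full pipeline on
cohorts of 9 subjects × 200 ROIs × 1800 frames, Cholesky checks at
20 ROIs × 50 000 samples, and oracle comparisons on ≤12-point inputs —
sizes chosen so the whole suite completes in seconds while every code
path, including the bootstraps and the τ scan, is exercised end to end.
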