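# Methods notes

## Signal model and preprocessing

A trial is a 360-frame pupil-diameter series at 60 fps, normalized to an
individual baseline: D_RATIO(t) = 100 · diameter(t) / baseline. The
baseline is treated as an input supplied with the raw data rather than
estimated (the window over which a study defines it — pre-stimulus gray
screen vs. session mean — varies across labs; the generator emits one per
participant).

Cleaning applies two marking rules in a fixed order, interpolating after
each:

1. **Jump rule.** Scanning frames in order with a reference r = the last
   accepted frame: a frame deviating from r by more than 10% opens a
   missing interval; the interval closes at the first frame back within 5%
   of r, which is retained and becomes the new reference. The reference is
   deliberately the last *accepted* frame, not the previous raw frame —
   comparing consecutive artifactual frames would let a blink "end" inside
   itself, since mid-blink frames change slowly.
2. **Range rule.** Frames with D_RATIO strictly below 40 or strictly above
   160 are missing; the boundary values are physiologically possible and
   retained.

Gaps of at most 30 frames (500 ms, twice the minimum latency of a
stimulus-driven pupil change) are filled with PCHIP — shape-preserving
piecewise cubic Hermite interpolation, which cannot overshoot monotone
anchors. Longer gaps, and gaps touching the first or last frame (no anchor
on one side), exclude the trial: PCHIP extrapolation is unreliable and
conservative exclusion is cheaper than a wrong tail. All thresholds are
strict inequalities (a 30-frame gap is kept, a 31-frame gap excludes).

Degenerate inputs: a trace with fewer than two non-missing frames is
excluded (not an exception); preprocessing an already-clean trace is a
no-op, and the pipeline is idempotent on its own output.

## The 45-feature summary

Point features (max, min, mean, population std, start = frame 1, finish =
frame 360, peak = max over frames 51–360 and the two latencies), ratio
features (drop ratio = min/start, recovery ratio = finish/start, peak
ratio = peak/min, reaction extent = drop + recovery ratio), dispersion
(stability = mean/std, range, baseline deviation = start − mean), and the
cumulative family: AUPC (discrete sum of D_RATIO, rectangle rule with unit
frame spacing — chosen over the trapezoid for bit-reproducibility; the
difference is a negligible boundary term) and the total absolute
frame-to-frame change, each computed over the whole trial, over six
60-frame intervals, and on the trace rescaled so its start equals 100
(`s_` variants, which are exactly invariant to rescaling the input).

Conventions that the definitions leave open, fixed here: latencies are
1-based frame indices with ties broken earliest; "after frame 50" means
frames 51–360 inclusive; "compared to" ratios are quotients;
response duration = peak latency − drop latency and may be negative; the
frame-to-frame difference crossing an interval boundary belongs to the
later interval, so the six interval change sums partition the total. A
zero-variance trace has no defined stability and is excluded (the
remaining 44 values are still reported on the exclusion error for
diagnostics) — exclusion, not sentinel imputation, keeps the feature table
fully finite.

## Stimulus properties

Spatial frequency is scored as the mean absolute first difference between
neighboring pixels, averaged over the horizontal and vertical directions —
the simplest gradient-based measure of local intensity variation. Its
absolute scale is arbitrary (intensity levels per pixel on a 0–255 image);
the meaningful output is the ordinal level. Level boundaries come either
from a reference set of five ranges (with gap scores mapped to the nearer
range) or from equal-frequency quintiles of the observed score
distribution. Luminance is normalized by an additive shift to mean 127.5
with one clipping correction — only the mean is constrained, so histogram
matching would be over-engineering. Arousal ratings live on a 1–7 scale
(8–9 excluded by stimulus-set design) and bin as 1–2 low / 3–5 mid / 6–7
high.

## DTW clustering

Stimulus-averaged curves (frame-wise mean over participants) are clustered
by DTW k-means with k = 6. The local cost is the squared pointwise
difference; the distance is the square root of the optimal accumulated
cost over unconstrained monotone paths (the common convention in DTW
clustering implementations). Initialization draws k distinct curves by
seeded sampling; centroids update by DTW barycenter averaging capped at 10
inner iterations, taking the best of {current centroid, barycenter,
medoid} so the within-cluster cost never increases; assignment ties break
toward the lower cluster index. Clusters are renumbered in ascending order
of mean pupil size. Clustering is exploratory: its outputs never feed the
classifiers, which the module boundary enforces.

## Classification harness

Folds are participant partitions (seeded shuffle, near-equal sizes), so no
participant appears on both sides of a fold. SMOTE
(x + u·(x_nn − x), u ~ U[0,1], k nearest minority neighbors, k ∈ 1–5) runs
only on training folds; every synthetic row carries the index of its
source row, which tests use to prove no test-row leakage. Eleven
classifier identifiers are accepted; all use library defaults with the run
seed pinned (no tuning). The easy-ensemble, balanced-random-forest and
RUSBoost variants are implemented in-package as random-undersampling
ensembles over scikit-learn base learners (AdaBoost bags, balanced
bootstrap trees, and undersampled SAMME boosting respectively).
Scale-sensitive models (logistic, SVM, k-NN) see z-scores fit on the
training fold; tree ensembles see raw features.

Positive valence is the positive class everywhere. Undefined metric ratios
(zero denominators, e.g. a single-class test fold) are reported as 0 with
a flag rather than raised, so degenerate folds stay averageable. AUC is
the rank statistic with half credit for ties. The P4 score is the harmonic
mean of precision, recall, specificity and NPV; it is symmetric under
simultaneous class swap and confusion-matrix transpose. Mean ROC curves
are vertical averages of per-fold TPR at 101 evenly spaced FPR points with
pinned endpoints.

The stratified grid runs every requested classifier × SMOTE-k × fold-count
configuration within each arousal × SF cell; a cell needs both classes
present with at least as many samples per class as the smallest fold
count, otherwise it is reported absent, never imputed. The per-cell best
configuration is recorded under both selection conventions — highest mean
AUC and highest mean P4 — because both are legitimate and give different
winners often enough to matter.

Feature attribution: for linear models the per-sample contribution of
feature j is coef_j · (x_j − mean x_j) on the model's (standardized) input
scale — the exact Shapley value of a linear model under feature
independence; for other families, seeded permutation importance on AUC,
with only per-feature magnitudes reported and the method labeled.

## Synthetic data: what it emulates, and what it does not

The generator emulates a passive-viewing study of 40 participants × 50
stimuli (25 positive / 25 negative). Each trial follows a deterministic
template — a half-cosine fall from 100 to 100 − C at frame t_min, then
exponential relaxation toward a plateau P_end with time constant τ = 80
frames — plus AR(1) Gaussian noise (sd 2 D_RATIO units, coefficient 0.8;
autocorrelated noise keeps the change-sum features informative, which
white noise would not).

Defaults (positive, negative): constriction depth C (20, 25), time to
minimum t_min (55, 45) frames, plateau P_end (103, 99), with negative
trials also getting 1.5× noise. `valence_effect_size` scales every pair's
deviation from its midpoint, so 0 collapses the classes exactly.
Negative valence is thus expressed as faster, deeper constriction, weaker
recovery and more unstable traces. Spatial frequency lowers the sustained
response (gain 2.5 D_RATIO per SD of the SF score, applied to both C and
P_end), and arousal scales response amplitude (×1.1 per level).

Real pupil data are dominated by within-participant, between-trial
variability, and the generator reproduces that: a per-participant effect
multiplier (sd 0.3) and amplitude multiplier (sd 0.1), a per-trial effect
multiplier (sd 0.6), additive per-trial jitter on latency (6 frames),
depth and plateau (2 D_RATIO units each), and a lognormal noise-scale
jitter (sd 0.25). Without the trial-level terms the classes are almost
perfectly separable from single features, which no pupillometry dataset
is; with them, pooled grouped-CV logistic AUC sits near 0.94 at the
default effect size, near 0.5 at effect size 0, and stratified arousal ×
SF cells exceed the pooled run — the qualitative regime the pipeline is
designed to exhibit. Stimulus metadata mirror a 50-image reference design:
SF level counts 7/11/10/11/11 drawn within the five reference ranges,
arousal level counts 7/25/18, luminance ≈ 127.5 ± 0.07.

Artifacts: Poisson blinks (rate 0.5/trial, durations uniform on 3–36
frames, attenuation to 10–35% of signal so post-normalization values fall
below the 40 gate) and Poisson single-frame spikes (rate 0.5/trial,
±12–25%), placed interior to the trial. Under these defaults roughly
80–90% of trials survive the 30-frame rule, the regime a real study of
this design reports.

Not emulated: actual image content and semantics, gaze position and
foreshortening, luminance transients, slow drift and vigilance effects,
and any nonlinear coupling between arousal and valence. Passing tests
therefore demonstrate the pipeline's correctness and its behavior under
the assumed effect structure — not that real pupil data carry a valence
signal of this size.

## Determinism and problem sizes

Every random operation takes an explicit seed (canonical default 1004).
Trial seeds derive from (study seed, participant index, stimulus index),
so datasets are byte-reproducible and sub-designs are subsets of the full
design. The test suite runs the full 40 × 50 study for the end-to-end
checks and smaller designs (8–20 participants) elsewhere; the acceptance
script runs the full study once, with the stratified sweep restricted to
logistic regression, 5 folds, SMOTE k ∈ {none, 5} — the representative
configuration — while `grid_run` exposes the full 11 × 6 × 3 sweep for
users who want it.

## Known limitations

* The jump-rule reference convention and the marking/interpolation
  ordering are documented choices; studies that define them differently
  will mark slightly different frame sets near artifact onsets.
* DTW k-means with seeded draw initialization can converge to local
  optima; results are deterministic per seed but not globally optimal.
* The undersampling ensembles are faithful in spirit but not line-by-line
  ports of any particular reference implementation; expect small metric
  differences from other packages' versions.
* SF scores are relative; comparing absolute scores across image sizes or
  bit depths is not meaningful, only the ordinal levels are.
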