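# pupilvalence

Tools for asking whether pupil dynamics alone can tell positive from
negative emotional stimuli — once the visual confounds that usually swamp
that signal are controlled.

Pupil diameter responds to far more than emotion: luminance, the spatial
frequency (SF) of the image, and emotional arousal all drive constriction
and dilation. `pupilvalence` implements a complete analysis pipeline for
passive-viewing pupillometry studies (monocular recording at 60 fps, 360
frames ≈ 6 s per trial) in which those factors are measured, binned, and
explicitly stratified before valence classification is attempted. It is
aimed at psychophysiologists and methods researchers who want a tested,
reproducible reference implementation — including a synthetic-data module
so the entire pipeline runs and is testable without any participant data.

## What it does

1. **Trace cleaning** (`pupilvalence.preprocess`). Each trial is expressed
   relative to an individual baseline (D_RATIO, baseline = 100). Frames
   whose D_RATIO changes by more than 10% from the last accepted frame are
   marked missing until the signal returns within 5% of that reference;
   frames below 40 or above 160 are marked missing; gaps of ≤ 30 frames are
   filled by shape-preserving PCHIP interpolation and longer gaps exclude
   the trial.
2. **Feature extraction** (`pupilvalence.features`). 45 waveform features
   per valid trial: extrema, latencies, ratios (drop ratio = min/start,
   recovery ratio = finish/start), dispersion, and a cumulative family —
   the area under the pupil curve AUPC = Σₜ D_RATIO(t) and the total
   variation Σₜ |ΔD_RATIO(t)|, each over the whole trial, per 60-frame
   interval, and in a start-normalized (`s_`) variant.
3. **Stimulus properties** (`pupilvalence.stimulus`). A gradient-based SF
   score (mean absolute neighbor intensity difference, averaged over the
   horizontal and vertical directions), luminance normalization to a mean
   of 127.5, arousal binning (ratings 1–2 low / 3–5 mid / 6–7 high) and
   five ordinal SF levels.
4. **Exploratory DTW clustering** (`pupilvalence.dtw`). Dynamic-time-warping
   k-means (k = 6, barycenter averaging) over stimulus-averaged curves,
   with per-cluster SF summaries. Cluster labels are descriptive only and
   never enter classification.
5. **Leakage-safe classification** (`pupilvalence.classify`). Group k-fold
   cross-validation at the participant level, SMOTE oversampling applied
   strictly inside training folds, eleven classifiers (logistic regression
   through gradient-boosted trees and undersampling ensembles), six
   standard metrics plus the P4 composite
   P4 = 4 / (1/precision + 1/recall + 1/specificity + 1/NPV),
   arousal × SF stratified grid runs, vertically averaged ROC curves, and
   per-feature attribution.
6. **Synthetic study generation** (`pupilvalence.synthetic`). 40
   participants × 50 stimuli by default, with a constriction-then-recovery
   waveform whose depth, timing, recovery and variability differ by
   valence, SF-dependent sustained constriction, arousal-dependent
   amplitude, participant and trial heterogeneity, AR(1) noise, and
   injectable blink/spike artifacts.

## Worked example

```python
import pupilvalence as pv
from pupilvalence.io import stimuli_frame
from pupilvalence.types import RunConfig

cfg = pv.GeneratorConfig(seed=1004, n_participants=10)
trials, stimuli = pv.generate_dataset(cfg)
kept, report = pv.preprocess_dataset(trials)
print(f"kept {report.n_kept}/{report.n_total} trials after cleaning")

table = pv.extract_feature_table(kept, stimuli_frame(stimuli))
print(f"feature table: {table.shape[0]} trials x 45 features")

res = pv.run_cv(table, RunConfig(classifier_name="logistic", cv_folds=5))
print(
    "group 5-fold logistic: "
    f"AUC {res.mean['auc']:.3f} +/- {res.sd['auc']:.3f}, "
    f"accuracy {res.mean['accuracy']:.3f}, P4 {res.mean['p4']:.3f}"
)
```

Output:

```
kept 411/500 trials after cleaning
feature table: 411 trials x 45 features
group 5-fold logistic: AUC 0.961 +/- 0.010, accuracy 0.893, P4 0.892
```

The cleaning step drops trials with blink dropouts longer than 30 frames
(89 of 500 here). The cross-validated AUC is the probability that a
randomly chosen positive-valence trial scores above a negative one, with
folds split by participant so no individual contributes to both training
and evaluation of the same model.

The same stages are scriptable from a shell:

```
pupilvalence simulate --out data/ --seed 1004
pupilvalence preprocess --in data/trials.csv --out data/clean.csv --report data/report.json
pupilvalence features --in data/clean.csv --meta data/stimuli.csv --out data/features.csv
pupilvalence classify --features data/features.csv --model logistic --folds 5 --out data/run.json
pupilvalence grid --features data/features.csv --models logistic --out data/grid.csv
```

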