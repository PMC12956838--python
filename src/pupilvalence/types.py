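"""Shared domain types for the pupillometry valence pipeline.

Conventions used throughout the package:

* Pupil traces are sampled at 60 frames/second; a trial is 360 frames (6 s)
  by default.
* ``D_RATIO`` is pupil size relative to an individual baseline fixed at 100
  (dimensionless percent-of-baseline).
* Frame indices are 1-based in every external contract (frame 1 = trial
  start, frame 360 = trial end); arrays are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "RawPupilTrace",
    "PupilTrace",
    "StimulusMeta",
    "GapRecord",
    "MetricSet",
    "RunConfig",
    "Valence",
    "ArousalLevel",
    "ConfigError",
    "FormatError",
    "ValidationError",
]

Valence = Literal["positive", "negative"]
ArousalLevel = Literal["low", "mid", "high"]

DEFAULT_SEED = 1004
DEFAULT_FRAMES = 360

#: Accepted classifier identifiers: the ten-model roster plus a plain bagging
#: ensemble, which appears alongside them in stratified comparisons.
CLASSIFIER_NAMES = (
    "logistic",
    "svm",
    "decision_tree",
    "random_forest",
    "knn",
    "xgboost",
    "lightgbm",
    "easy_ensemble",
    "balanced_random_forest",
    "rusboost",
    "bagging",
)


class ConfigError(ValueError):
    """Raised for out-of-range or malformed run configuration."""


class FormatError(ValueError):
    """Raised for structurally invalid input files (missing columns etc.)."""


class ValidationError(ValueError):
    """Raised when file contents violate a documented contract."""


@dataclass
class RawPupilTrace:
    """One trial's raw pupil diameters in device units.

    ``baseline`` is the individual reference diameter that maps to
    D_RATIO = 100; it is supplied with the data (the synthetic generator
    emits it) rather than estimated here.
    """

    participant_id: str
    stimulus_id: str
    values: np.ndarray
    baseline: float
    sampling_rate: float = 60.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("trace values must be a non-empty 1-d array")
        if not self.baseline > 0:
            raise ValidationError(
                f"baseline must be positive, got {self.baseline!r} "
                f"({self.participant_id}/{self.stimulus_id})"
            )
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


@dataclass
class PupilTrace:
    """Baseline-normalized pupil trace (D_RATIO units, baseline = 100)."""

    participant_id: str
    stimulus_id: str
    d_ratio: np.ndarray
    missing_mask: np.ndarray | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        self.d_ratio = np.asarray(self.d_ratio, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.d_ratio.size, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.size != self.d_ratio.size:
            raise ValidationError("missing_mask length must match d_ratio")

    @property
    def n_frames(self) -> int:
        return int(self.d_ratio.size)

    def copy(self) -> "PupilTrace":
        return replace(
            self, d_ratio=self.d_ratio.copy(), missing_mask=self.missing_mask.copy()
        )


@dataclass
class GapRecord:
    """A contiguous run of missing frames, 1-based inclusive endpoints."""

    start_frame: int
    end_frame: int
    cause: Literal["jump", "range"]

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame or self.start_frame < 1:
            raise ValidationError("gap endpoints must satisfy 1 <= start <= end")


@dataclass
class StimulusMeta:
    """Per-stimulus metadata: valence label, arousal, and visual properties."""

    stimulus_id: str
    valence: Valence
    arousal_rating: int
    arousal_level: ArousalLevel
    sf_value: float
    sf_level: int
    mean_luminance: float

    def __post_init__(self) -> None:
        if self.valence not in ("positive", "negative"):
            raise ValidationError(f"unknown valence {self.valence!r}")
        if not 1 <= int(self.arousal_rating) <= 7:
            raise ValidationError(
                f"arousal_rating must be in 1..7, got {self.arousal_rating}"
            )
        if self.arousal_level not in ("low", "mid", "high"):
            raise ValidationError(f"unknown arousal_level {self.arousal_level!r}")
        if not 1 <= int(self.sf_level) <= 5:
            raise ValidationError(f"sf_level must be in 1..5, got {self.sf_level}")


@dataclass
class MetricSet:
    """Fold-level (or fold-averaged) classification metrics.

    Undefined ratios (zero denominator) are reported as 0.0 and the metric
    name is recorded in ``flags`` so degenerate folds stay averageable
    instead of crashing a run.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float
    p4: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    flags: frozenset[str] = field(default_factory=frozenset)

    METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1", "auc", "p4")

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in self.METRIC_NAMES}
        d.update(tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn,
                 flags=sorted(self.flags))
        return d


@dataclass
class RunConfig:
    """Run-wide configuration with the pipeline's canonical defaults."""

    random_seed: int = DEFAULT_SEED
    cv_folds: int = 5
    smote_k_neighbors: int | None = None
    classifier_name: str = "logistic"
    frames_per_trial: int = DEFAULT_FRAMES
    jump_start_pct: float = 10.0
    jump_end_pct: float = 5.0
    d_ratio_low: float = 40.0
    d_ratio_high: float = 160.0
    max_gap_frames: int = 30
    dtw_k: int = 6

    def __post_init__(self) -> None:
        if self.cv_folds not in (3, 5, 7):
            raise ConfigError(f"cv_folds must be one of 3, 5, 7; got {self.cv_folds}")
        if self.smote_k_neighbors is not None and not (
            1 <= int(self.smote_k_neighbors) <= 5
        ):
            raise ConfigError(
                f"smote_k_neighbors must be in 1..5 or none; got {self.smote_k_neighbors}"
            )
        if self.classifier_name not in CLASSIFIER_NAMES:
            raise ConfigError(f"unknown classifier {self.classifier_name!r}")
        for name in ("jump_start_pct", "jump_end_pct", "d_ratio_low",
                     "d_ratio_high", "max_gap_frames", "frames_per_trial"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.jump_end_pct > self.jump_start_pct:
            raise ConfigError("jump_end_pct must not exceed jump_start_pct")
        if not self.d_ratio_low < 100 < self.d_ratio_high:
            raise ConfigError("d_ratio bounds must bracket the baseline (100)")
        if self.dtw_k < 1:
            raise ConfigError("dtw_k must be >= 1")
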