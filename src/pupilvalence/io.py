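"""Readers and writers for the pipeline's plain-text interchange formats.

Canonical formats (all frame indices 1-based):

* trials CSV (long): ``participant_id,stimulus_id,frame,value,baseline``
* stimulus metadata CSV: ``stimulus_id,valence,arousal_rating,arousal_level,
  sf_value,sf_level,mean_luminance``
* features CSV: ``participant_id,stimulus_id,<45 feature columns>``
* metrics JSON: per-fold values plus mean/sd per metric
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    FormatError,
    MetricSet,
    RawPupilTrace,
    RunConfig,
    StimulusMeta,
    ValidationError,
)

_FRAME_HEADER = "# frame indices are 1-based (frame 1 = trial start)\n"

TRIAL_COLUMNS = ["participant_id", "stimulus_id", "frame", "value", "baseline"]
META_COLUMNS = [
    "stimulus_id", "valence", "arousal_rating", "arousal_level",
    "sf_value", "sf_level", "mean_luminance",
]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trials(path) -> list[RawPupilTrace]:
    """Read a long-format trials CSV into one :class:`RawPupilTrace` per trial.

    Frames must be contiguous (1..n) within each (participant, stimulus)
    pair; violations raise :class:`ValidationError` naming the trial.
    """
    df = _read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trials CSV missing column(s): {missing}")
    traces = []
    for (pid, sid), grp in df.groupby(
        ["participant_id", "stimulus_id"], sort=True
    ):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        expected = np.arange(1, len(frames) + 1)
        if not np.array_equal(frames, expected):
            raise ValidationError(
                f"trial {pid}/{sid}: frames not contiguous from 1 to {len(frames)}"
            )
        baseline = grp["baseline"].to_numpy()
        if not np.all(baseline == baseline[0]):
            raise ValidationError(f"trial {pid}/{sid}: baseline not constant")
        traces.append(
            RawPupilTrace(
                participant_id=str(pid),
                stimulus_id=str(sid),
                values=grp["value"].to_numpy(dtype=float),
                baseline=float(baseline[0]),
            )
        )
    return traces


def write_trials(traces: list[RawPupilTrace], path) -> None:
    rows = []
    for tr in traces:
        n = tr.n_frames
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "stimulus_id": tr.stimulus_id,
                    "frame": np.arange(1, n + 1),
                    "value": tr.values,
                    "baseline": tr.baseline,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=TRIAL_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(_FRAME_HEADER)
        df.to_csv(fh, index=False)


def read_stimuli(path) -> list[StimulusMeta]:
    df = _read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stimulus CSV missing column(s): {missing}")
    return [
        StimulusMeta(
            stimulus_id=str(r.stimulus_id),
            valence=r.valence,
            arousal_rating=int(r.arousal_rating),
            arousal_level=r.arousal_level,
            sf_value=float(r.sf_value),
            sf_level=int(r.sf_level),
            mean_luminance=float(r.mean_luminance),
        )
        for r in df.itertuples()
    ]


def write_stimuli(stimuli: list[StimulusMeta], path) -> None:
    df = pd.DataFrame([vars(s) for s in stimuli], columns=META_COLUMNS)
    df.to_csv(path, index=False)


def stimuli_frame(stimuli: list[StimulusMeta]) -> pd.DataFrame:
    """Stimulus metadata as a DataFrame indexed by stimulus_id."""
    return pd.DataFrame([vars(s) for s in stimuli], columns=META_COLUMNS).set_index(
        "stimulus_id", drop=False
    )


def write_features(rows: pd.DataFrame, path) -> None:
    """Write a feature table (keys + 45 feature columns) to CSV.

    All feature values must be finite; a NaN anywhere is a contract
    violation (invalid trials should have been dropped upstream).
    """
    from .features import FEATURE_NAMES  # local import avoids a cycle

    missing = [c for c in FEATURE_NAMES if c not in rows.columns]
    if missing:
        raise FormatError(f"feature table missing column(s): {missing}")
    block = rows[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if block.size and not np.all(np.isfinite(block)):
        raise ValidationError("feature table contains non-finite values")
    cols = ["participant_id", "stimulus_id", *FEATURE_NAMES]
    extra = [c for c in rows.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write(_FRAME_HEADER)
        rows[cols + extra].to_csv(fh, index=False)


def read_features(path) -> pd.DataFrame:
    return _read_csv(path)


def write_metrics(per_fold: list[MetricSet], path) -> None:
    """Serialize per-fold metrics plus mean/sd per metric to JSON."""
    payload = {
        "folds": [m.as_dict() for m in per_fold],
        "mean": {},
        "sd": {},
    }
    for name in MetricSet.METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
        payload["mean"][name] = float(vals.mean())
        payload["sd"][name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    Path(path).write_text(json.dumps(payload, indent=2))


def load_config(path) -> RunConfig:
    """Load a YAML key-value config; unspecified keys take RunConfig defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise FormatError("config file must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config key(s): {sorted(unknown)}")
    if data.get("smote_k_neighbors") in ("none", "None"):
        data["smote_k_neighbors"] = None
    return RunConfig(**data)
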