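"""The 45-feature summary of a cleaned pupil trace.

Point features (max, min, start, finish, peak after frame 50, latencies),
ratio features (drop, recovery, peak ratio), dispersion features (std,
stability, range), and a cumulative family: AUPC (area under the pupil
curve, discrete sum of D_RATIO over the trial), change_sum (total absolute
frame-to-frame variation), each computed globally, per 60-frame interval
(six intervals), and in a start-normalized variant (``s_``) in which the
trace is rescaled so its first frame equals 100.

Conventions (fixed for reproducibility):

* latencies are 1-based frame indices; ties broken by the earliest frame;
* "after frame 50" means frames 51..360 inclusive;
* std is the population standard deviation;
* AUPC uses the rectangle rule (plain sum, unit frame spacing);
* the frame-to-frame difference crossing an interval boundary belongs to
  the *later* interval, so the six interval change sums partition the total;
* response_duration = peak_latency − drop_latency and may be negative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import PupilTrace, ValidationError

__all__ = ["FEATURE_NAMES", "FeatureError", "extract_features", "extract_feature_table"]

logger = logging.getLogger(__name__)

N_INTERVALS = 6
PEAK_WINDOW_START = 51  # 1-based first frame of the post-onset peak window

FEATURE_NAMES: tuple[str, ...] = (
    "max", "min", "mean", "std", "start", "finish",
    "peak", "peak_ratio", "peak_latency", "drop_latency",
    "drop_ratio", "recovery_ratio", "response_duration", "reaction_extent",
    "stability", "range", "baseline_deviation",
    "aupc", "s_aupc",
    *[f"aupc{i}" for i in range(1, 7)],
    *[f"s_aupc{i}" for i in range(1, 7)],
    "change_sum", "s_change_sum",
    *[f"change_sum{i}" for i in range(1, 7)],
    *[f"s_change_sum{i}" for i in range(1, 7)],
)
assert len(FEATURE_NAMES) == 45


class FeatureError(ValueError):
    """Trace unusable for feature extraction (e.g. zero variance).

    When the failure is the zero-variance stability rule, the other 44
    features are still well-defined and are attached as ``partial``.
    """

    def __init__(self, message: str, partial: dict | None = None):
        super().__init__(message)
        self.partial = partial or {}


def _interval_slices(n: int) -> list[slice]:
    if n % N_INTERVALS != 0:
        raise ValidationError(
            f"trial length {n} not divisible into {N_INTERVALS} equal intervals"
        )
    step = n // N_INTERVALS
    return [slice(i * step, (i + 1) * step) for i in range(N_INTERVALS)]


def _cumulative(d: np.ndarray, slices: list[slice]) -> dict:
    """AUPC and change-sum family for one (possibly rescaled) trace."""
    out = {"aupc": float(d.sum())}
    diffs = np.abs(np.diff(d))  # diffs[t-1] = |d[t] - d[t-1]|, 0-based
    out["change_sum"] = float(diffs.sum())
    for i, sl in enumerate(slices, start=1):
        out[f"aupc{i}"] = float(d[sl].sum())
        # differences with target frame inside interval i (boundary-crossing
        # difference assigned to the later interval)
        lo = max(sl.start, 1)
        out[f"change_sum{i}"] = float(diffs[lo - 1 : sl.stop - 1].sum())
    return out


def extract_features(trace: PupilTrace) -> dict[str, float]:
    """Compute the 45 named features of a valid trace.

    Raises :class:`FeatureError` if the trace has zero variance (stability
    undefined) or a non-positive start; such trials are excluded downstream
    rather than imputed.
    """
    if not trace.valid:
        raise FeatureError("trace is flagged invalid")
    d = np.asarray(trace.d_ratio, dtype=float)
    if not np.all(np.isfinite(d)):
        raise FeatureError("trace contains non-finite values")
    n = d.size
    if n < PEAK_WINDOW_START:
        raise ValidationError(f"trace too short ({n} frames) for the peak window")
    slices = _interval_slices(n)

    start = float(d[0])
    if start <= 0:
        raise FeatureError("start value must be positive")
    std = float(d.std())  # population std

    f: dict[str, float] = {}
    f["max"] = float(d.max())
    f["min"] = float(d.min())
    f["mean"] = float(d.mean())
    f["std"] = std
    f["start"] = start
    f["finish"] = float(d[-1])
    window = d[PEAK_WINDOW_START - 1 :]
    f["peak"] = float(window.max())
    f["peak_latency"] = float(PEAK_WINDOW_START + int(np.argmax(window)))
    f["drop_latency"] = float(1 + int(np.argmin(d)))
    f["peak_ratio"] = f["peak"] / f["min"]
    f["drop_ratio"] = f["min"] / start
    f["recovery_ratio"] = f["finish"] / start
    f["response_duration"] = f["peak_latency"] - f["drop_latency"]
    f["reaction_extent"] = f["drop_ratio"] + f["recovery_ratio"]
    f["range"] = f["max"] - f["min"]
    f["baseline_deviation"] = start - f["mean"]

    f.update(_cumulative(d, slices))
    scaled = _cumulative(d * (100.0 / start), slices)
    f.update({f"s_{k}": v for k, v in scaled.items()})

    if std == 0.0:
        # the other 44 features are well-defined; expose them on the error
        raise FeatureError(
            "zero-variance trace: stability undefined",
            partial={k: v for k, v in f.items() if k != "stability"},
        )
    f["stability"] = f["mean"] / std

    vals = np.array([f[name] for name in FEATURE_NAMES])
    if not np.all(np.isfinite(vals)):
        raise FeatureError("non-finite feature value")
    return {name: f[name] for name in FEATURE_NAMES}


def extract_feature_table(
    traces: list[PupilTrace], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Feature rows for all usable traces, joined with stimulus metadata.

    ``metadata`` must be indexed by (or contain) ``stimulus_id`` covering
    every trace; traces that fail the finite-value / variance checks are
    dropped and logged, mirroring the exclusion of feature-level missing
    values.
    """
    meta = metadata.set_index("stimulus_id", drop=False) if (
        metadata.index.name != "stimulus_id"
    ) else metadata
    rows = []
    n_dropped = 0
    for tr in traces:
        if tr.stimulus_id not in meta.index:
            raise ValidationError(f"unknown stimulus_id {tr.stimulus_id!r}")
        try:
            feats = extract_features(tr)
        except FeatureError as exc:
            n_dropped += 1
            logger.info(
                "excluding trial %s/%s: %s", tr.participant_id, tr.stimulus_id, exc
            )
            continue
        m = meta.loc[tr.stimulus_id]
        rows.append(
            {
                "participant_id": tr.participant_id,
                "stimulus_id": tr.stimulus_id,
                **feats,
                "valence": m["valence"],
                "arousal_level": m["arousal_level"],
                "sf_level": int(m["sf_level"]),
            }
        )
    if n_dropped:
        logger.info("dropped %d trial(s) with undefined features", n_dropped)
    cols = ["participant_id", "stimulus_id", *FEATURE_NAMES,
            "valence", "arousal_level", "sf_level"]
    return pd.DataFrame(rows, columns=cols)
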