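"""Rule-based pupil-trace cleaning.

The pipeline normalizes each trial to its individual baseline (D_RATIO,
baseline = 100) and then applies, in order:

1. jump marking — a frame whose D_RATIO differs from the last accepted
   frame by more than 10% opens a missing interval; the interval closes at
   the first frame back within 5% of that same reference (which is retained
   and becomes the new reference);
2. PCHIP interpolation of the resulting gaps;
3. range gating — frames with D_RATIO below 40 or above 160 are missing;
4. PCHIP interpolation again.

Any gap longer than 30 frames, or a gap touching the first or last frame
(no anchor on one side), excludes the trial rather than extrapolating.
Percent-change references are the last *accepted* frame, not the previous
raw frame, so an artifact cannot terminate inside itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .types import GapRecord, PupilTrace, RawPupilTrace, RunConfig, ValidationError

__all__ = [
    "normalize_to_baseline",
    "mark_jump_artifacts",
    "mark_range_violations",
    "interpolate_gaps",
    "preprocess_trial",
    "preprocess_dataset",
    "PreprocessReport",
]


def normalize_to_baseline(raw: RawPupilTrace) -> PupilTrace:
    """Express a raw trace as D_RATIO: 100 x value / individual baseline."""
    if not raw.baseline > 0:
        raise ValidationError("baseline must be positive")
    return PupilTrace(
        participant_id=raw.participant_id,
        stimulus_id=raw.stimulus_id,
        d_ratio=100.0 * raw.values / raw.baseline,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) 0-based inclusive indices."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        runs.append((int(idx[s]), int(idx[e])))
    return runs


def mark_jump_artifacts(
    trace: PupilTrace, start_pct: float = 10.0, end_pct: float = 5.0
) -> list[GapRecord]:
    """Mark abrupt frame-to-frame changes as missing (in place).

    Scans frames in order keeping a reference ``r`` = last accepted frame's
    D_RATIO. A frame deviating from ``r`` by more than ``start_pct`` percent
    opens a missing run; the run ends at the first frame within ``end_pct``
    percent of ``r``, which is retained and becomes the new reference.
    Frames already missing are skipped and never serve as reference.
    """
    d = trace.d_ratio
    miss = trace.missing_mask
    n = d.size
    new_missing = np.zeros(n, dtype=bool)
    ref = None
    in_gap = False
    for t in range(n):
        if miss[t]:
            continue
        if ref is None:
            ref = d[t]
            continue
        rel = abs(d[t] - ref) / ref * 100.0
        if in_gap:
            if rel <= end_pct:
                in_gap = False
                ref = d[t]
            else:
                new_missing[t] = True
        else:
            if rel > start_pct:
                in_gap = True
                new_missing[t] = True
            else:
                ref = d[t]
    trace.missing_mask |= new_missing
    return [
        GapRecord(start_frame=s + 1, end_frame=e + 1, cause="jump")
        for s, e in _runs(new_missing)
    ]


def mark_range_violations(
    trace: PupilTrace, low: float = 40.0, high: float = 160.0
) -> list[GapRecord]:
    """Mark frames with D_RATIO strictly below ``low`` or above ``high``.

    Boundary values (exactly 40 or 160) are retained.
    """
    bad = (trace.d_ratio < low) | (trace.d_ratio > high)
    new = bad & ~trace.missing_mask
    trace.missing_mask |= bad
    return [
        GapRecord(start_frame=s + 1, end_frame=e + 1, cause="range")
        for s, e in _runs(new)
    ]


def interpolate_gaps(trace: PupilTrace, max_gap: int = 30) -> PupilTrace:
    """Fill missing runs of <= ``max_gap`` frames by PCHIP; else invalidate.

    Shape-preserving piecewise-cubic Hermite interpolation through the
    non-missing frames; monotone anchor segments are never overshot.  A gap
    longer than ``max_gap``, or one touching the first/last frame (no
    anchor on one side), sets ``valid=False`` — the trial is excluded, not
    extrapolated.  Valid traces come back with zero missing frames.
    """
    miss = trace.missing_mask
    if not miss.any():
        return trace
    n = trace.n_frames
    anchors = np.flatnonzero(~miss)
    if anchors.size < 2:
        trace.valid = False
        return trace
    for s, e in _runs(miss):
        if (e - s + 1) > max_gap or s == 0 or e == n - 1:
            trace.valid = False
            return trace
    interp = PchipInterpolator(anchors, trace.d_ratio[anchors])
    gaps = np.flatnonzero(miss)
    trace.d_ratio[gaps] = interp(gaps)
    trace.missing_mask[:] = False
    return trace


def preprocess_trial(
    raw: RawPupilTrace, config: RunConfig | None = None
) -> tuple[PupilTrace, list[GapRecord]]:
    """Normalize and clean one trial; returns the trace and its gap records.

    Stages run in the documented order (jump marking, interpolate, range
    gating, interpolate); the valid flag reflects both stages.
    """
    cfg = config or RunConfig()
    trace = normalize_to_baseline(raw)
    gaps = mark_jump_artifacts(trace, cfg.jump_start_pct, cfg.jump_end_pct)
    trace = interpolate_gaps(trace, cfg.max_gap_frames)
    if trace.valid:
        gaps += mark_range_violations(trace, cfg.d_ratio_low, cfg.d_ratio_high)
        trace = interpolate_gaps(trace, cfg.max_gap_frames)
    return trace, gaps


@dataclass
class PreprocessReport:
    """Dataset-level cleaning summary."""

    n_total: int = 0
    n_kept: int = 0
    n_excluded: int = 0
    gaps: dict = field(default_factory=dict)  # (pid, sid) -> list[GapRecord]
    excluded: list = field(default_factory=list)  # (pid, sid)


def preprocess_dataset(
    raws: list[RawPupilTrace], config: RunConfig | None = None
) -> tuple[list[PupilTrace], PreprocessReport]:
    """Clean every trial; return valid traces and a summary report."""
    report = PreprocessReport(n_total=len(raws))
    kept = []
    for raw in raws:
        trace, gaps = preprocess_trial(raw, config)
        key = (raw.participant_id, raw.stimulus_id)
        if gaps:
            report.gaps[key] = gaps
        if trace.valid:
            kept.append(trace)
        else:
            report.excluded.append(key)
    report.n_kept = len(kept)
    report.n_excluded = len(report.excluded)
    return kept, report
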