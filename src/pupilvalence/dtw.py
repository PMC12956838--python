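"""Dynamic-time-warping distance and DTW k-means for pupil curves.

Exploratory only: cluster labels describe temporal-shape families of
stimulus-averaged pupil responses and are never fed to the classifiers.

Conventions: local cost is the squared pointwise difference accumulated
over monotone warping paths with unit steps (match / insert / delete); the
reported distance is the square root of the optimal accumulated cost.  No
warping window.  Centroids are updated by DTW barycenter averaging (DBA)
with a medoid fallback, so the within-cluster cost never increases.
Clusters are renumbered in ascending order of mean pupil size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .types import PupilTrace, ValidationError

__all__ = [
    "dtw_distance",
    "dtw_kmeans",
    "average_curve_per_stimulus",
    "cluster_sf_summary",
    "ClusterResult",
]

logger = logging.getLogger(__name__)


@njit(cache=True)
def _dtw_cost(a, b):  # pragma: no cover - exercised via dtw_distance
    n, m = a.size, b.size
    big = np.inf
    prev = np.full(m + 1, big)
    cur = np.full(m + 1, big)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = big
        for j in range(1, m + 1):
            c = (a[i - 1] - b[j - 1]) ** 2
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _dtw_path(a, b):  # pragma: no cover - exercised via _dba_update
    """Optimal warping path as (i, j) index pairs; diagonal-preferring ties."""
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = (a[i - 1] - b[j - 1]) ** 2
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    path = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        path[k, 0] = i - 1
        path[k, 1] = j - 1
        k += 1
        if i == 1 and j == 1:
            break
        diag = D[i - 1, j - 1] if i > 1 and j > 1 else np.inf
        up = D[i - 1, j] if i > 1 else np.inf
        left = D[i, j - 1] if j > 1 else np.inf
        if diag <= up and diag <= left:
            i -= 1
            j -= 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
    return path[:k]


def dtw_distance(a, b) -> float:
    """DTW distance between two finite 1-d sequences (see module docstring)."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("sequences must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("sequences must be finite")
    return float(np.sqrt(_dtw_cost(a, b)))


def _dba_update(seqs: list[np.ndarray], centroid: np.ndarray, max_iter: int = 10):
    """DTW barycenter averaging seeded at ``centroid``."""
    center = centroid.copy()
    for _ in range(max_iter):
        sums = np.zeros(center.size)
        counts = np.zeros(center.size)
        for s in seqs:
            path = _dtw_path(center, s)
            for i, j in path:
                sums[i] += s[j]
                counts[i] += 1
        new = sums / np.maximum(counts, 1)
        if np.allclose(new, center, atol=1e-10):
            center = new
            break
        center = new
    return center


@dataclass
class ClusterResult:
    """DTW k-means output, clusters numbered 1..k by ascending mean level."""

    k: int
    assignments: dict  # stimulus_id -> cluster index (1-based)
    centroids: list  # k arrays, frames long
    cluster_mean_level: list  # mean pupil size of member curves per cluster
    inertia: float  # sum of within-cluster DTW distances


def _within_cost(seqs, centroid) -> float:
    return sum(float(np.sqrt(_dtw_cost(centroid, s))) for s in seqs)


def dtw_kmeans(
    curves: dict,
    k: int = 6,
    seed: int = 1004,
    max_iter: int = 10,
    dba_iter: int = 10,
) -> ClusterResult:
    """Cluster curves (stimulus_id -> 1-d array) by DTW k-means.

    Initialization draws k distinct curves by seeded sampling (ties broken
    by stimulus_id order); assignment is by nearest centroid under DTW;
    centroid update takes the best of {current centroid, DBA barycenter,
    medoid}, so the objective is non-increasing.  Deterministic given seed.
    """
    ids = sorted(curves)
    seqs = [np.ascontiguousarray(curves[i], dtype=np.float64) for i in ids]
    n = len(seqs)
    if n < k:
        raise ValidationError(f"need at least k={k} curves, got {n}")
    rng = np.random.default_rng(seed)
    centroids = [seqs[i].copy() for i in rng.choice(n, size=k, replace=False)]

    labels = np.full(n, -1)
    for _ in range(max_iter):
        dist = np.empty((n, k))
        for ci, cent in enumerate(centroids):
            for si, s in enumerate(seqs):
                dist[si, ci] = np.sqrt(_dtw_cost(cent, s))
        new_labels = dist.argmin(axis=1)  # ties -> lowest cluster index
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for ci in range(k):
            members = [seqs[i] for i in np.flatnonzero(labels == ci)]
            if not members:
                continue
            candidates = [centroids[ci], _dba_update(members, centroids[ci], dba_iter)]
            candidates += [m for m in members]  # medoid fallback
            costs = [_within_cost(members, c) for c in candidates]
            centroids[ci] = candidates[int(np.argmin(costs))].copy()

    # renumber ascending by cluster mean pupil level (members; else centroid)
    means = np.array(
        [
            np.mean([seqs[i].mean() for i in np.flatnonzero(labels == ci)])
            if np.any(labels == ci)
            else centroids[ci].mean()
            for ci in range(k)
        ]
    )
    order = np.argsort(means, kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    assignments = {sid: relabel[int(lab)] for sid, lab in zip(ids, labels)}
    centroids_sorted = [centroids[int(old)] for old in order]
    inertia = sum(
        float(np.sqrt(_dtw_cost(centroids_sorted[cl - 1], curves_i)))
        for curves_i, cl in zip(seqs, (assignments[s] for s in ids))
    )
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=centroids_sorted,
        cluster_mean_level=[float(means[int(old)]) for old in order],
        inertia=inertia,
    )


def average_curve_per_stimulus(traces: list[PupilTrace]) -> dict:
    """Frame-wise mean D_RATIO curve per stimulus over its valid traces."""
    groups: dict[str, list[np.ndarray]] = {}
    for tr in traces:
        if not tr.valid:
            logger.warning(
                "skipping invalid trace %s/%s", tr.participant_id, tr.stimulus_id
            )
            continue
        groups.setdefault(tr.stimulus_id, []).append(tr.d_ratio)
    return {sid: np.mean(np.vstack(arrs), axis=0) for sid, arrs in groups.items()}


def cluster_sf_summary(result: ClusterResult, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean spatial frequency and mean pupil level.

    ``metadata`` must cover every clustered stimulus (columns stimulus_id,
    sf_value).  Absent (empty) clusters are omitted with a warning.
    """
    meta = metadata.set_index("stimulus_id") if (
        metadata.index.name != "stimulus_id"
    ) else metadata
    rows = []
    for cl in range(1, result.k + 1):
        sids = [s for s, c in result.assignments.items() if c == cl]
        if not sids:
            logger.warning("cluster %d is empty", cl)
            continue
        missing = [s for s in sids if s not in meta.index]
        if missing:
            raise ValidationError(f"metadata missing stimuli: {missing}")
        rows.append(
            {
                "cluster": cl,
                "n_stimuli": len(sids),
                "mean_sf": float(meta.loc[sids, "sf_value"].mean()),
                "mean_level": result.cluster_mean_level[cl - 1],
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "n_stimuli", "mean_sf", "mean_level"])
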