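"""Stimulus visual-property scoring and level binning.

Spatial frequency (SF) is quantified by a gradient-based score: the mean
absolute intensity difference between horizontally adjacent pixels and
between vertically adjacent pixels, averaged over the two directions.  The
score is relative (unit: intensity levels per pixel on a 0-255 scale); the
meaningful output is the ordinal SF level (1-5).

Arousal ratings come in on a 1-7 ordinal scale (ratings 8-9 are excluded
by design) and are binned low (1-2) / mid (3-5) / high (6-7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ArousalLevel, ValidationError

__all__ = [
    "spatial_frequency",
    "normalize_luminance",
    "assign_arousal_level",
    "assign_sf_level",
    "SFLevelBoundaries",
    "quantile_sf_levels",
]

#: Observed SF score ranges of the five levels in the reference stimulus set
#: (level -> (low, high)).  Scores falling in the small gaps between ranges
#: map to the nearer boundary's level.
REFERENCE_SF_RANGES = (
    (5.40, 6.95),
    (7.19, 11.06),
    (11.08, 13.30),
    (13.32, 17.68),
    (17.93, 47.82),
)


def spatial_frequency(image: np.ndarray) -> float:
    """Gradient-based SF score of a grayscale image (intensities 0-255).

    score = (mean |horizontal first difference| + mean |vertical first
    difference|) / 2.  Non-negative; zero iff the image is constant.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValidationError("image must be a 2-d array of at least 2x2 pixels")
    horiz = np.abs(np.diff(img, axis=1)).mean()
    vert = np.abs(np.diff(img, axis=0)).mean()
    return float((horiz + vert) / 2.0)


def normalize_luminance(image: np.ndarray, target_mean: float = 127.5) -> np.ndarray:
    """Shift an image so its mean pixel intensity matches ``target_mean``.

    Additive shift followed by clipping to [0, 255]; if clipping moved the
    mean, the shift is applied once more.  The result's mean is within 0.5
    of the target for any input whose mass is not pinned to one extreme.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValidationError("empty image")
    out = np.clip(img + (target_mean - img.mean()), 0.0, 255.0)
    if abs(out.mean() - target_mean) > 1e-9:
        out = np.clip(out + (target_mean - out.mean()), 0.0, 255.0)
    return out


def assign_arousal_level(rating: int) -> ArousalLevel:
    """Bin a 1-7 arousal rating: 1-2 low, 3-5 mid, 6-7 high.

    Ratings outside 1-7 are rejected (the extreme 8-9 band is excluded from
    the stimulus design).
    """
    r = int(rating)
    if not 1 <= r <= 7:
        raise ValidationError(f"arousal rating must be in 1..7, got {rating}")
    if r <= 2:
        return "low"
    if r <= 5:
        return "mid"
    return "high"


@dataclass(frozen=True)
class SFLevelBoundaries:
    """Four ordered cutpoints splitting the SF score axis into 5 levels.

    ``level(score) = 1 + #{c in cutpoints : score > c}``, i.e. intervals are
    (-inf, c1], (c1, c2], ..., (c4, +inf).
    """

    cutpoints: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValidationError("SF cutpoints must be ordered")

    @classmethod
    def reference(cls) -> "SFLevelBoundaries":
        """Cutpoints at the midpoints of the gaps between the reference ranges."""
        cuts = tuple(
            (REFERENCE_SF_RANGES[i][1] + REFERENCE_SF_RANGES[i + 1][0]) / 2.0
            for i in range(4)
        )
        return cls(cutpoints=cuts)

    @classmethod
    def from_scores(cls, scores) -> "SFLevelBoundaries":
        """Equal-frequency (quintile) cutpoints from a score collection."""
        s = np.asarray(scores, dtype=float)
        if s.size < 5:
            raise ValidationError("need at least 5 scores for quantile boundaries")
        return cls(cutpoints=tuple(np.quantile(s, [0.2, 0.4, 0.6, 0.8])))


def assign_sf_level(score: float, boundaries: SFLevelBoundaries | None = None) -> int:
    """Map a continuous SF score to its ordinal level 1-5."""
    b = boundaries or SFLevelBoundaries.reference()
    return 1 + int(sum(score > c for c in b.cutpoints))


def quantile_sf_levels(scores) -> np.ndarray:
    """Rank-based equal-frequency levels (1-5) for a collection of scores.

    Level counts differ by at most one; equal scores keep their input order
    (stable sort), and a higher score never gets a lower level.
    """
    s = np.asarray(scores, dtype=float)
    order = np.argsort(s, kind="stable")
    ranks = np.empty(s.size, dtype=int)
    ranks[order] = np.arange(s.size)
    return (ranks * 5 // s.size) + 1
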