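"""Data-gap report around the cut-off.

A cut score placed inside a wide empty interval between adjacent observed
scores is easier to defend: no student sits near the boundary.  This module
lists the widest such intervals inside a score window — by default the
judges' [c_min, c_max] range, the region the detailed chart covers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .scores import ScoreSet


@dataclass(frozen=True)
class Gap:
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class GapReport:
    """Widest empty intervals between adjacent distinct scores, widest first."""

    gaps: tuple[Gap, ...]
    window: tuple[float, float]

    def as_rows(self) -> list[dict[str, float]]:
        return [
            {"lower": g.lower, "upper": g.upper, "width": g.width}
            for g in self.gaps
        ]


def find_gaps(score_set: ScoreSet, window_low: float, window_high: float,
              top_k: int = 3) -> GapReport:
    """Top ``top_k`` widest intervals between adjacent distinct scores.

    Only intervals with both endpoints inside [window_low, window_high]
    count.  Ties are broken by lower score ascending.  Fewer than two
    distinct scores in the window yields an empty report, not an error.
    """
    if window_low >= window_high:
        raise ValidationError(
            f"gap window [{window_low}, {window_high}] is empty")
    if top_k < 1:
        raise ValidationError(f"top_k must be positive, got {top_k}")
    inside = [s for s in score_set.distinct()
              if window_low <= s <= window_high]
    gaps = [Gap(lo, hi) for lo, hi in zip(inside, inside[1:]) if hi > lo]
    gaps.sort(key=lambda g: (-g.width, g.lower))
    return GapReport(tuple(gaps[:top_k]), window=(window_low, window_high))
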