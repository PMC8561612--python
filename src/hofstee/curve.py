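"""The cumulative-percentage polyline.

Convention (load-bearing for the whole package): the curve has one vertex
per distinct observed score v at

    y(v) = 100 * (# scores <= v) / n,

i.e. rank-based "at or below" percentages, with consecutive vertices joined
by straight segments.  For a 181-student cohort whose 6th and 7th ascending
scores are 53.5 and 54.5 this puts vertices at (53.5, 3.31) and
(54.5, 3.87) after 2-dp display rounding — the coordinates a practitioner
reads off the chart.  No synthetic (0, 0) origin vertex is prepended: the
curve starts at the minimum observed score, so no cut-off can fall below
it.  Midpoint percentile conventions such as 100*(k - 0.5)/n are
deliberately not offered; they would shift every vertex and hence the
cut-off.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .scores import ScoreSet


@dataclass(frozen=True)
class CurveVertex:
    x: float  # score
    y: float  # cumulative percent of students at or below x


@dataclass(frozen=True)
class CumulativeCurve:
    """Ordered polyline of (score, cumulative percent) vertices."""

    vertices: tuple[CurveVertex, ...]
    n_students: int

    def __post_init__(self) -> None:
        if not self.vertices:
            raise ValidationError("cumulative curve has no vertices")
        xs = self.xs
        ys = self.ys
        if np.any(np.diff(xs) <= 0):
            raise ValidationError("curve vertices must strictly increase in x")
        if np.any(np.diff(ys) < 0):
            raise ValidationError("curve vertices must not decrease in y")
        if abs(ys[-1] - 100.0) > 1e-9:
            raise ValidationError("curve must end at 100 percent")

    @property
    def xs(self) -> np.ndarray:
        return np.array([v.x for v in self.vertices])

    @property
    def ys(self) -> np.ndarray:
        return np.array([v.y for v in self.vertices])

    def segments(self) -> list[tuple[CurveVertex, CurveVertex]]:
        return list(zip(self.vertices[:-1], self.vertices[1:]))

    @property
    def x_range(self) -> tuple[float, float]:
        return self.vertices[0].x, self.vertices[-1].x


def build_cumulative_curve(score_set: ScoreSet) -> CumulativeCurve:
    """Build the cumulative curve from a sorted score set.

    One vertex per distinct score; duplicates collapse into a single vertex
    whose y counts every student at or below that score.  All arithmetic is
    full double precision; 2-dp rounding is display-only.
    """
    arr = np.asarray(score_set.scores)
    n = arr.size
    distinct, counts = np.unique(arr, return_counts=True)
    cumulative = np.cumsum(counts)
    vertices = tuple(
        CurveVertex(float(x), float(100.0 * k / n))
        for x, k in zip(distinct, cumulative)
    )
    return CumulativeCurve(vertices, n_students=n)


def curve_value_at(curve: CumulativeCurve, x: float) -> float:
    """Linear interpolation of the cumulative percent at score ``x``.

    ``x`` must lie within the curve's x-range; at a vertex the vertex y is
    returned exactly.
    """
    lo, hi = curve.x_range
    if not lo <= x <= hi:
        raise ValidationError(
            f"x={x} outside the curve's score range [{lo}, {hi}]")
    return float(np.interp(x, curve.xs, curve.ys))


def export_curve_csv(curve: CumulativeCurve, path: str | Path) -> Path:
    """Write the vertices as a two-column audit CSV (score, cumulative %)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["score", "cumulative_percent"])
        for v in curve.vertices:
            writer.writerow([repr(v.x), repr(v.y)])
    return path
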