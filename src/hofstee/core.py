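"""Line AB construction and the algebraic cut-off scan.

The Hofstee compromise is the point where line AB — drawn from
A = (c_min, f_max) to B = (c_max, f_min) — crosses the cumulative
percentage curve.  The curve has no closed-form equation, but it is a
polyline, so the crossing is found exactly by scanning its segments in
ascending score order and solving each segment's line against AB
algebraically; the first segment whose solution lies within the segment's
x-range (and on AB itself, taken as a closed segment) yields the cut-off.
When the crossing lands exactly on a shared vertex, both adjacent segments
produce the identical point, so which one reports it is immaterial.

Because AB is non-increasing (f_max >= f_min) while the curve is
non-decreasing, at most one crossing exists whenever AB has a strictly
negative slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .curve import CumulativeCurve, curve_value_at
from .errors import NoIntersectionError, ValidationError
from .judges import HofsteeParameters

#: absolute tolerance for segment-membership tests, so a crossing that
#: coincides with a vertex is accepted from either adjacent segment
EPS = 1e-9


def round_display(value: float, places: int = 2) -> float:
    """Round for display: half away from zero (37.615 -> 37.62)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LineSegment:
    """A closed segment in (score, percent) coordinates."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if self.x1 == self.x2 and self.y1 == self.y2:
            raise ValidationError("degenerate segment: endpoints coincide")

    @property
    def x_lo(self) -> float:
        return min(self.x1, self.x2)

    @property
    def x_hi(self) -> float:
        return max(self.x1, self.x2)


@dataclass(frozen=True)
class CutoffResult:
    """The Hofstee cut-off: full-precision location plus provenance."""

    cutoff_x: float           # the pass/fail score
    cutoff_y: float           # expected percent of students failing
    segment_index: int        # which cumulative segment produced it (-1: fallback)
    fallback_used: bool = False

    @property
    def display_cutoff(self) -> float:
        return round_display(self.cutoff_x)

    @property
    def display_fail_percent(self) -> float:
        return round_display(self.cutoff_y)


def hofstee_line(params: HofsteeParameters) -> LineSegment:
    """Line AB: A = (c_min, f_max) down to B = (c_max, f_min).

    A vertical segment (c_min == c_max) or horizontal segment
    (f_min == f_max) is allowed; only the fully degenerate case where AB
    collapses to a point is rejected.
    """
    if params.c_min == params.c_max and params.f_min == params.f_max:
        raise ValidationError(
            "line AB degenerates to a point: c_min == c_max and "
            "f_min == f_max")
    return LineSegment(params.c_min, params.f_max, params.c_max, params.f_min)


def intersect_segments(a: LineSegment, b: LineSegment) -> tuple[float, float] | None:
    """Unique point lying on both closed segments, or ``None``.

    Parallel non-collinear and non-overlapping collinear pairs give
    ``None``.  Collinear overlapping pairs return the smallest-x point of
    the overlap (for the Hofstee use this is the lowest passing standard
    consistent with the judgement).  Membership tests use an absolute
    tolerance of ``EPS`` so vertex-coincident crossings are not lost to
    rounding.
    """
    rx, ry = a.x2 - a.x1, a.y2 - a.y1
    sx, sy = b.x2 - b.x1, b.y2 - b.y1
    denom = rx * sy - ry * sx
    qpx, qpy = b.x1 - a.x1, b.y1 - a.y1

    if denom == 0.0:
        if qpx * ry - qpy * rx != 0.0:
            return None  # parallel, distinct lines
        # collinear: overlap in the parameter of segment a
        rr = rx * rx + ry * ry
        t0 = (qpx * rx + qpy * ry) / rr
        t1 = t0 + (sx * rx + sy * ry) / rr
        lo, hi = min(t0, t1), max(t0, t1)
        lo, hi = max(lo, 0.0), min(hi, 1.0)
        if lo > hi + EPS:
            return None
        # smallest-x point of the overlap
        t = lo if rx >= 0 else hi
        return (a.x1 + t * rx, a.y1 + t * ry)

    t = (qpx * sy - qpy * sx) / denom
    u = (qpx * ry - qpy * rx) / denom
    span = max(abs(rx), abs(ry), abs(sx), abs(sy), 1.0)
    tol = EPS / span
    if -tol <= t <= 1.0 + tol and -tol <= u <= 1.0 + tol:
        return (a.x1 + t * rx, a.y1 + t * ry)
    return None


def _point_on_segment(px: float, py: float, seg: LineSegment) -> bool:
    rx, ry = seg.x2 - seg.x1, seg.y2 - seg.y1
    cross = (px - seg.x1) * ry - (py - seg.y1) * rx
    if abs(cross) > EPS * max(abs(rx), abs(ry), 1.0):
        return False
    dot = (px - seg.x1) * rx + (py - seg.y1) * ry
    return -EPS <= dot <= rx * rx + ry * ry + EPS


def _diagnose_no_intersection(curve: CumulativeCurve,
                              ab: LineSegment) -> NoIntersectionError:
    """Explain why AB never meets the curve, with an actionable hint."""
    lo = max(curve.x_range[0], ab.x_lo)
    hi = min(curve.x_range[1], ab.x_hi)
    if lo > hi:
        # score range disjoint from the judges' window: the failing
        # fraction over the window is a constant 0% or 100%
        if curve.x_range[0] > ab.x_hi:
            return NoIntersectionError(
                "every student scored above the judges' window "
                f"[{ab.x_lo:g}, {ab.x_hi:g}]: no cut in the window fails "
                "anyone; consider lowering f_min or raising c_max",
                direction="below")
        return NoIntersectionError(
            "every student scored below the judges' window "
            f"[{ab.x_lo:g}, {ab.x_hi:g}]: any cut in the window fails "
            "everyone; consider raising f_max or lowering c_min",
            direction="above")

    def ab_y(x: float) -> float:
        if ab.x1 == ab.x2:
            return min(ab.y1, ab.y2)
        return ab.y1 + (ab.y2 - ab.y1) * (x - ab.x1) / (ab.x2 - ab.x1)

    mid = 0.5 * (lo + hi)
    diffs = [curve_value_at(curve, x) - ab_y(x) for x in (lo, mid, hi)]
    if all(d > 0 for d in diffs):
        return NoIntersectionError(
            "the cumulative curve lies entirely above line AB: more "
            "students would fail than f_max allows at every candidate "
            "score; consider raising f_max or lowering c_min",
            direction="above")
    return NoIntersectionError(
        "the cumulative curve lies entirely below line AB: fewer students "
        "would fail than f_min requires at every candidate score; consider "
        "lowering f_min or raising c_max", direction="below")


def _corner_fallback(curve: CumulativeCurve, ab: LineSegment) -> CutoffResult:
    """Nearest AB endpoint in y-distance to the curve, used only on request."""
    lo, hi = curve.x_range
    best: tuple[float, float, float] | None = None
    for ex, ey in ((ab.x1, ab.y1), (ab.x2, ab.y2)):
        cx = min(max(ex, lo), hi)
        dist = abs(curve_value_at(curve, cx) - ey)
        if best is None or dist < best[0]:
            best = (dist, cx, ey)
    assert best is not None
    return CutoffResult(best[1], curve_value_at(curve, best[1]),
                        segment_index=-1, fallback_used=True)


def find_cutoff(curve: CumulativeCurve, ab: LineSegment,
                fallback: str | None = None) -> CutoffResult:
    """Scan the cumulative segments in ascending x for the crossing with AB.

    Returns the first (and, for strictly decreasing AB, only) segment whose
    algebraic intersection with AB lies within the segment's x-range and on
    AB as a closed segment.  Raises :class:`NoIntersectionError` with a
    directional diagnostic when no segment qualifies, unless
    ``fallback="corner"`` requests substitution of the nearest AB endpoint.

    A single-vertex curve (all students share one score) degenerates to the
    point (score, 100); the cut-off exists only if AB passes through it.
    """
    vertices = curve.vertices
    if len(vertices) == 1:
        v = vertices[0]
        if _point_on_segment(v.x, v.y, ab):
            return CutoffResult(v.x, v.y, segment_index=0)
    else:
        for index, (v1, v2) in enumerate(curve.segments()):
            point = intersect_segments(
                ab, LineSegment(v1.x, v1.y, v2.x, v2.y))
            if point is None:
                continue
            x_i, y_i = point
            if v1.x - EPS <= x_i <= v2.x + EPS:
                return CutoffResult(float(x_i), float(y_i),
                                    segment_index=index)
    if fallback == "corner":
        return _corner_fallback(curve, ab)
    raise _diagnose_no_intersection(curve, ab)


def compute_cutoff(curve: CumulativeCurve, params: HofsteeParameters,
                   fallback: str | None = None) -> CutoffResult:
    """Convenience wrapper: build AB from the parameters and scan."""
    return find_cutoff(curve, hofstee_line(params), fallback=fallback)
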