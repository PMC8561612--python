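"""Shared fixtures: two reference cohorts and a brute-force cut-off oracle.

Both cohorts are synthetic stand-ins constructed so that their cumulative
curves contain, as consecutive vertices, the exact segment coordinates a
practitioner would read off the published worked examples; the cut-off they
produce is therefore checkable against an independently known value.
"""

from __future__ import annotations

import numpy as np
import pytest

from hofstee import (CumulativeCurve, LineSegment, ScoreSet,
                     build_cumulative_curve)

#: five judges' (c_min, c_max, f_min, f_max) quadruples; column means are
#: (45, 55, 3, 7), giving AB from (45, 7) to (55, 3)
FIVE_JUDGE_PANEL = [
    (50, 60, 1, 4),
    (44, 56, 3, 8),
    (41, 52, 4, 8),
    (45, 54, 5, 8),
    (45, 53, 2, 7),
]


def demo_cohort_scores() -> ScoreSet:
    """100 students whose curve contains the segment (30, 8)-(40, 17).

    8 distinct low scores ending at 30 (8% at or below 30), nine students
    tied at 40 (17% at or below 40), then 83 distinct high scores.  The
    line AB built from (35, 45, 6, 18) crosses inside that segment at
    x = 79/2.1.
    """
    values = [10, 13, 16, 19, 22, 25, 28, 30] + [40] * 9
    values += list(np.linspace(41, 100, 83))
    return ScoreSet(tuple(values), source_label="synthetic demo cohort")


def class_cohort_scores() -> ScoreSet:
    """Synthetic 181-student class, scores 43-97, whose 6th and 7th
    ascending scores are 53.5 and 54.5 (curve vertices (53.5, 3.31) and
    (54.5, 3.87) at 2-dp display)."""
    values = [43, 45, 47, 49, 51, 53.5, 54.5] + list(np.linspace(55, 97, 174))
    return ScoreSet(tuple(values), source_label="synthetic 181-student class")


@pytest.fixture
def demo_cohort() -> ScoreSet:
    return demo_cohort_scores()


@pytest.fixture
def class_cohort() -> ScoreSet:
    return class_cohort_scores()


def ab_value_at(ab: LineSegment, x: float) -> float:
    if ab.x1 == ab.x2:
        raise ValueError("vertical AB has no y(x) form")
    return ab.y1 + (ab.y2 - ab.y1) * (x - ab.x1) / (ab.x2 - ab.x1)


def brute_force_cutoff(curve: CumulativeCurve, ab: LineSegment,
                       step: float = 1e-4) -> tuple[float, float] | None:
    """Independent oracle: dense scan for the sign change of
    curve(x) - AB(x) over the overlap of the curve's range and AB's x-span,
    refined by bisection.  Returns (x, y) or None when no crossing exists.
    """
    lo = max(curve.x_range[0], ab.x_lo)
    hi = min(curve.x_range[1], ab.x_hi)
    if lo > hi:
        return None
    xs = np.arange(lo, hi + step, step)
    xs[-1] = hi
    ab_ys = ab.y1 + (ab.y2 - ab.y1) * (xs - ab.x1) / (ab.x2 - ab.x1)
    diff = np.interp(xs, curve.xs, curve.ys) - ab_ys
    exact = np.flatnonzero(np.abs(diff) < 1e-12)
    if exact.size:
        x = float(xs[exact[0]])
        return x, float(np.interp(x, curve.xs, curve.ys))
    signs = np.sign(diff)
    change = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    if change.size == 0:
        return None
    a, b = float(xs[change[0]]), float(xs[change[0] + 1])
    fa = float(np.interp(a, curve.xs, curve.ys)) - ab_value_at(ab, a)
    for _ in range(80):
        mid = 0.5 * (a + b)
        fm = float(np.interp(mid, curve.xs, curve.ys)) - ab_value_at(ab, mid)
        if fa * fm <= 0:
            b = mid
        else:
            a, fa = mid, fm
    x = 0.5 * (a + b)
    return x, float(np.interp(x, curve.xs, curve.ys))


def curve_of(values) -> CumulativeCurve:
    return build_cumulative_curve(ScoreSet(tuple(values)))
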