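"""Line AB construction, segment intersection, and the cut-off scan."""

import numpy as np
import pytest

from hofstee import (CumulativeCurve, CurveVertex, HofsteeParameters,
                     LineSegment, NoIntersectionError, ScoreSet,
                     ValidationError, build_cumulative_curve, compute_cutoff,
                     find_cutoff, hofstee_line, intersect_segments)
from tests.conftest import FIVE_JUDGE_PANEL, brute_force_cutoff, curve_of
from hofstee import JudgePanel, aggregate_panel


def params(c_min, c_max, f_min, f_max, source="direct"):
    return HofsteeParameters(c_min, c_max, f_min, f_max, source=source)


class TestHofsteeLine:
    def test_endpoints_are_cmin_fmax_to_cmax_fmin(self):
        ab = hofstee_line(params(35, 45, 6, 18))
        assert (ab.x1, ab.y1, ab.x2, ab.y2) == (35, 18, 45, 6)

    def test_aggregated_panel_line(self):
        agg = aggregate_panel(JudgePanel.from_quadruples(FIVE_JUDGE_PANEL))
        ab = hofstee_line(agg)
        assert (ab.x1, ab.y1, ab.x2, ab.y2) == (45, 7, 55, 3)

    def test_vertical_line_allowed(self):
        ab = hofstee_line(params(40, 40, 5, 15))
        assert (ab.x1, ab.y1, ab.x2, ab.y2) == (40, 15, 40, 5)

    def test_point_degenerate_rejected(self):
        with pytest.raises(ValidationError, match="point"):
            hofstee_line(params(40, 40, 5, 5))


class TestIntersectSegments:
    def test_published_demo_intersection(self):
        point = intersect_segments(LineSegment(35, 18, 45, 6),
                                   LineSegment(30, 8, 40, 17))
        assert point is not None
        assert point[0] == pytest.approx(79 / 2.1, abs=1e-12)

    def test_published_class_intersection(self):
        point = intersect_segments(LineSegment(45, 7, 55, 3),
                                   LineSegment(53.5, 3.31, 54.5, 3.87))
        assert point is not None
        assert point[0] == pytest.approx(53.802083333, abs=1e-9)

    def test_parallel_segments_do_not_intersect(self):
        assert intersect_segments(LineSegment(0, 0, 1, 1),
                                  LineSegment(0, 1, 1, 2)) is None

    def test_crossing_lines_with_disjoint_segments(self):
        # the infinite lines cross at (0.5, 0.5), outside both segments
        assert intersect_segments(LineSegment(0, 0, 0.2, 0.2),
                                  LineSegment(0.8, 0.2, 1.0, 0.0)) is None

    def test_collinear_overlap_returns_smallest_x(self):
        point = intersect_segments(LineSegment(0, 5, 10, 5),
                                   LineSegment(4, 5, 20, 5))
        assert point == (4.0, 5.0)

    def test_collinear_disjoint_returns_none(self):
        assert intersect_segments(LineSegment(0, 5, 3, 5),
                                  LineSegment(4, 5, 8, 5)) is None

    def test_shared_endpoint_is_found(self):
        point = intersect_segments(LineSegment(0, 0, 1, 1),
                                   LineSegment(1, 1, 2, 0))
        assert point == pytest.approx((1.0, 1.0))

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            LineSegment(3, 3, 3, 3)


class TestFindCutoff:
    def test_demo_cohort_cutoff(self, demo_cohort):
        curve = build_cumulative_curve(demo_cohort)
        result = compute_cutoff(curve, params(35, 45, 6, 18))
        assert result.display_cutoff == 37.62
        assert result.cutoff_x == pytest.approx(79 / 2.1, abs=1e-9)
        # the cut-off sits on the curve
        assert result.cutoff_y == pytest.approx(
            np.interp(result.cutoff_x, curve.xs, curve.ys), abs=1e-9)

    def test_class_cohort_cutoff_from_judge_panel(self, class_cohort):
        agg = aggregate_panel(JudgePanel.from_quadruples(FIVE_JUDGE_PANEL))
        result = compute_cutoff(build_cumulative_curve(class_cohort), agg)
        assert result.display_cutoff == 53.80
        assert 45 <= result.cutoff_x <= 55
        assert 3 <= result.cutoff_y <= 7

    def test_everyone_scores_high_curve_below_ab(self):
        curve = curve_of([90, 95, 100])
        with pytest.raises(NoIntersectionError) as info:
            find_cutoff(curve, hofstee_line(params(35, 45, 6, 18)))
        assert info.value.direction == "below"

    def test_everyone_scores_low_curve_above_ab(self):
        curve = curve_of(list(range(5, 45)))
        with pytest.raises(NoIntersectionError) as info:
            find_cutoff(curve, hofstee_line(params(35, 45, 2, 6)))
        assert info.value.direction == "above"

    def test_window_entirely_below_scores_counts_as_nobody_failing(self):
        curve = curve_of([60, 70, 80])
        with pytest.raises(NoIntersectionError) as info:
            find_cutoff(curve, hofstee_line(params(10, 30, 2, 6)))
        assert info.value.direction == "below"

    def test_window_entirely_above_scores_counts_as_everyone_failing(self):
        curve = curve_of([10, 20, 30])
        with pytest.raises(NoIntersectionError) as info:
            find_cutoff(curve, hofstee_line(params(60, 80, 2, 6)))
        assert info.value.direction == "above"

    def test_vertical_ab_takes_curve_value_at_cmin(self):
        curve = curve_of([1, 2, 3, 4])  # y(2.5) = 62.5
        result = find_cutoff(curve, hofstee_line(params(2.5, 2.5, 50, 80)))
        assert result.cutoff_x == 2.5
        assert result.cutoff_y == pytest.approx(62.5)

    def test_vertical_ab_outside_fail_band_is_no_intersection(self):
        curve = curve_of([1, 2, 3, 4])
        with pytest.raises(NoIntersectionError):
            find_cutoff(curve, hofstee_line(params(2.5, 2.5, 5, 20)))

    def test_cutoff_at_shared_vertex_identical_from_either_segment(self):
        # AB passes exactly through the vertex (2, 50)
        curve = curve_of([1, 2, 3, 4])
        result = find_cutoff(curve, LineSegment(1, 75, 3, 25))
        assert result.cutoff_x == pytest.approx(2.0, abs=1e-9)
        assert result.cutoff_y == pytest.approx(50.0, abs=1e-9)

    def test_corner_fallback_returns_nearest_ab_endpoint(self):
        curve = curve_of([90, 95, 100])
        result = find_cutoff(curve, hofstee_line(params(35, 45, 6, 18)),
                             fallback="corner")
        assert result.fallback_used
        assert result.segment_index == -1
        assert curve.x_range[0] <= result.cutoff_x <= curve.x_range[1]

    def test_single_score_cohort_without_crossing(self):
        curve = curve_of([50, 50, 50])
        with pytest.raises(NoIntersectionError):
            find_cutoff(curve, hofstee_line(params(40, 60, 2, 8)))


def random_configuration(rng):
    """A random cohort and a random valid (strictly sloped) AB line."""
    n = int(rng.integers(20, 300))
    seed = int(rng.integers(2**31))
    from hofstee import generate_synthetic_scores
    scores = generate_synthetic_scores(n, 1, 100, seed=seed)
    c_min = float(rng.uniform(5, 75))
    c_max = c_min + float(rng.uniform(0.5, 24))
    f_min = float(rng.uniform(0, 30))
    f_max = f_min + float(rng.uniform(0.5, 40))
    return scores, params(round(c_min, 3), round(c_max, 3),
                          round(f_min, 3), round(f_max, 3))


class TestCutoffProperties:
    def test_scan_matches_brute_force_oracle(self):
        """The algebraic scan and a dense-grid sign-change oracle agree on
        existence and location across random cohort/parameter draws."""
        rng = np.random.default_rng(2024)
        found = 0
        for _ in range(60):
            scores, p = random_configuration(rng)
            curve = build_cumulative_curve(scores)
            ab = hofstee_line(p)
            oracle = brute_force_cutoff(curve, ab)
            try:
                result = find_cutoff(curve, ab)
            except NoIntersectionError:
                assert oracle is None
                continue
            assert oracle is not None
            assert result.cutoff_x == pytest.approx(oracle[0], abs=1e-6)
            found += 1
        assert found >= 10  # the draw ranges produce plenty of crossings

    def test_crossing_is_unique(self):
        """curve(x) - AB(x) is strictly increasing over the window, so the
        sign changes at most once."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            scores, p = random_configuration(rng)
            curve = build_cumulative_curve(scores)
            ab = hofstee_line(p)
            lo = max(curve.x_range[0], ab.x_lo)
            hi = min(curve.x_range[1], ab.x_hi)
            if lo >= hi:
                continue
            xs = np.linspace(lo, hi, 5000)
            diff = np.interp(xs, curve.xs, curve.ys) - np.interp(
                xs, [ab.x_lo, ab.x_hi], sorted([ab.y1, ab.y2], reverse=True))
            signs = np.sign(diff[np.abs(diff) > 1e-12])
            changes = np.count_nonzero(signs[:-1] != signs[1:])
            assert changes <= 1

    def test_shuffle_invariance(self, demo_cohort):
        rng = np.random.default_rng(11)
        baseline = compute_cutoff(build_cumulative_curve(demo_cohort),
                                  params(35, 45, 6, 18))
        for _ in range(5):
            shuffled = ScoreSet(tuple(rng.permutation(demo_cohort.scores)))
            result = compute_cutoff(build_cumulative_curve(shuffled),
                                    params(35, 45, 6, 18))
            assert result == baseline

    def test_subdivision_invariance(self, demo_cohort):
        """Inserting a collinear midpoint vertex into any segment leaves
        the cut-off unchanged to 1e-9."""
        curve = build_cumulative_curve(demo_cohort)
        ab = hofstee_line(params(35, 45, 6, 18))
        baseline = find_cutoff(curve, ab)
        for index in range(len(curve.vertices) - 1):
            v1, v2 = curve.vertices[index], curve.vertices[index + 1]
            mid = CurveVertex(0.5 * (v1.x + v2.x), 0.5 * (v1.y + v2.y))
            refined = CumulativeCurve(
                curve.vertices[:index + 1] + (mid,) + curve.vertices[index + 1:],
                n_students=curve.n_students)
            result = find_cutoff(refined, ab)
            assert result.cutoff_x == pytest.approx(baseline.cutoff_x, abs=1e-9)
            assert result.cutoff_y == pytest.approx(baseline.cutoff_y, abs=1e-9)

    def test_translation_equivariance(self, demo_cohort):
        """Shifting every score and the score-axis parameters by delta
        shifts the cut-off by exactly delta."""
        delta = -7.25
        baseline = compute_cutoff(build_cumulative_curve(demo_cohort),
                                  params(35, 45, 6, 18))
        shifted_scores = ScoreSet(tuple(s + delta for s in demo_cohort.scores))
        shifted = compute_cutoff(build_cumulative_curve(shifted_scores),
                                 params(35 + delta, 45 + delta, 6, 18))
        assert shifted.cutoff_x == pytest.approx(baseline.cutoff_x + delta,
                                                 abs=1e-9)
        assert shifted.cutoff_y == pytest.approx(baseline.cutoff_y, abs=1e-9)

    def test_cutoff_always_inside_parameter_box(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            scores, p = random_configuration(rng)
            curve = build_cumulative_curve(scores)
            try:
                result = compute_cutoff(curve, p)
            except NoIntersectionError:
                continue
            assert p.c_min - 1e-9 <= result.cutoff_x <= p.c_max + 1e-9
            assert p.f_min - 1e-9 <= result.cutoff_y <= p.f_max + 1e-9
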