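import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from abdoprofile.errors import (
    DegenerateGeometryError,
    DomainError,
    NotOnCurveError,
    ValidationError,
)
from abdoprofile import geometry as g
from abdoprofile.geometry import (
    AreaModelCoefficients,
    Point2D,
    ProfileLandmarks,
    QuadraticBezier,
)

from conftest import random_curve, random_profile_landmarks
from oracles import (
    circumradius,
    dense_profile_polygon,
    fd_curvature,
    gl_arc_length,
    polyline_length,
    shoelace,
)

PARABOLA = QuadraticBezier(Point2D(-1, 1), Point2D(0, -1), Point2D(1, 1))  # y = x^2
STRAIGHT = QuadraticBezier(Point2D(0, 0), Point2D(0.5, 0), Point2D(1, 0))
PARABOLA_ARC = math.sqrt(5) + 0.5 * math.log(2 + math.sqrt(5))  # int sqrt(1+4x^2)


class TestBernstein:
    def test_endpoint(self):
        assert g.bernstein(0, 2, 0.0) == 1.0

    def test_midpoint(self):
        assert g.bernstein(1, 2, 0.5) == pytest.approx(0.5, abs=1e-15)

    def test_partition_of_unity(self):
        assert sum(g.bernstein(k, 5, 0.37) for k in range(6)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k,n,t", [(-1, 2, 0.5), (3, 2, 0.5), (0, 2, -0.1), (0, 2, 1.1)])
    def test_domain_errors(self, k, n, t):
        with pytest.raises(DomainError):
            g.bernstein(k, n, t)


class TestBezierPoint:
    def test_endpoints(self):
        c = QuadraticBezier(Point2D(1, 2), Point2D(3, 4), Point2D(5, 6))
        assert g.bezier_point(c, 0.0) == c.start
        assert g.bezier_point(c, 1.0) == c.end

    def test_quarter_weights(self):
        c = QuadraticBezier(Point2D(0, 0), Point2D(1, 0), Point2D(1, 1))
        assert g.bezier_point(c, 0.5) == pytest.approx((0.75, 0.25), abs=1e-15)

    def test_t_out_of_range(self):
        with pytest.raises(DomainError):
            g.bezier_point(STRAIGHT, 1.5)

    def test_degenerate_rejected(self):
        with pytest.raises(DomainError):
            QuadraticBezier(Point2D(0, 0), Point2D(1, 1), Point2D(0, 0))


class TestBezierGeneral:
    def test_linear_midpoint(self):
        p = g.bezier_general([Point2D(0, 0), Point2D(2, 4)], 0.5)
        assert p == pytest.approx((1, 2), abs=1e-15)

    def test_matches_quadratic(self, rng):
        c = random_curve(rng)
        for t in np.linspace(0, 1, 11):
            expect = g.bezier_point(c, t)
            got = g.bezier_general([c.start, c.control, c.end], t)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_too_few_controls(self):
        with pytest.raises(DomainError):
            g.bezier_general([Point2D(0, 0)], 0.5)

    def test_split_retraces_locus(self, rng):
        # de Casteljau halves re-evaluate onto the original curve
        c = random_curve(rng)
        left, right = g.decasteljau_split(c, 0.3)
        for u in np.linspace(0, 1, 17):
            pl = g.bezier_point(left, u)
            assert pl == pytest.approx(g.bezier_point(c, 0.3 * u), abs=1e-9)
            pr = g.bezier_point(right, u)
            assert pr == pytest.approx(g.bezier_point(c, 0.3 + 0.7 * u), abs=1e-9)


class TestSegments:
    def test_upper_controls(self, fixture_landmarks):
        seg = g.upper_segment(fixture_landmarks)
        assert seg.start == (0.0, 0.0)
        assert seg.control == fixture_landmarks.p5
        assert seg.end == fixture_landmarks.p3

    def test_lower_controls(self, fixture_landmarks):
        seg = g.lower_segment(fixture_landmarks)
        assert seg.start == fixture_landmarks.p3
        assert seg.control == fixture_landmarks.p6
        assert seg.end == fixture_landmarks.p2

    def test_upper_expanded_form_identity(self, fixture_landmarks):
        # t^2(x3-2x5) + 2x5 t equals the Bernstein evaluation
        lm = fixture_landmarks
        t = 0.25
        x = t * t * (lm.p3.x - 2 * lm.p5.x) + 2 * lm.p5.x * t
        y = t * t * (lm.p3.y - 2 * lm.p5.y) + 2 * lm.p5.y * t
        assert g.bezier_point(g.upper_segment(lm), t) == pytest.approx((x, y), abs=1e-12)

    def test_lower_expanded_form_identity(self, fixture_landmarks):
        lm = fixture_landmarks
        t = 0.6
        x3, y3 = lm.p3
        x6, y6 = lm.p6
        y2 = lm.p2.y
        x = t * t * (x3 - 2 * x6) + 2 * t * (x6 - x3) + x3
        y = t * t * (y2 + y3 - 2 * y6) + 2 * t * (y6 - y3) + y3
        assert g.bezier_point(g.lower_segment(lm), t) == pytest.approx((x, y), abs=1e-12)


class TestParamAtPoint:
    def test_start(self, rng):
        c = random_curve(rng)
        assert g.param_at_point(c, c.start) == pytest.approx(0.0, abs=1e-9)

    def test_round_trip(self, rng):
        c = random_curve(rng)
        pt = g.bezier_point(c, 0.42)
        assert g.param_at_point(c, pt) == pytest.approx(0.42, abs=1e-9)

    def test_off_curve_rejected(self, rng):
        c = random_curve(rng)
        pt = g.bezier_point(c, 0.4)
        off = Point2D(pt.x + 0.05 * c.scale(), pt.y)
        with pytest.raises(NotOnCurveError):
            g.param_at_point(c, off)

    def test_closed_forms_match_numeric(self, rng):
        for _ in range(100):
            lm = random_profile_landmarks(rng)
            t1_num = g.param_at_point(g.upper_segment(lm), lm.p1)
            t4_num = g.param_at_point(g.lower_segment(lm), lm.p4)
            try:
                assert g.t1_closed_form(lm) == pytest.approx(t1_num, abs=1e-6)
                assert g.t4_closed_form(lm) == pytest.approx(t4_num, abs=1e-6)
            except DegenerateGeometryError:
                pass  # vanishing denominator: numeric route is authoritative


class TestCurvature:
    def test_straight_line_zero(self):
        for t in (0.0, 0.3, 1.0):
            assert g.curvature(STRAIGHT, t) == 0.0

    def test_parabola_vertex(self):
        assert g.curvature(PARABOLA, 0.5) == pytest.approx(2.0, rel=1e-12)

    def test_fd_oracle(self, rng):
        for _ in range(50):
            c = random_curve(rng)
            k = g.curvature(c, 0.3)
            assert k == pytest.approx(fd_curvature(c, 0.3), rel=1e-6, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        c = random_curve(rng)
        th = 0.7
        ca, sa = math.cos(0.9), math.sin(0.9)
        move = lambda p: Point2D(ca * p.x - sa * p.y + 11, sa * p.x + ca * p.y - 4)
        c2 = QuadraticBezier(move(c.start), move(c.control), move(c.end))
        assert g.curvature(c2, th) == pytest.approx(g.curvature(c, th), rel=1e-9)

    def test_degenerate_speed(self):
        # control coincides with start: B'(0) = 0
        c = QuadraticBezier(Point2D(0, 0), Point2D(0, 0), Point2D(1, 1))
        with pytest.raises(DegenerateGeometryError):
            g.curvature(c, 0.0)


class TestOsculatingRadius:
    def test_parabola_vertex(self):
        assert g.osculating_radius(PARABOLA, 0.5) == pytest.approx(0.5, rel=1e-12)

    def test_reciprocal_identity(self, rng):
        c = random_curve(rng)
        k = g.curvature(c, 0.37)
        if k > 0:
            assert g.osculating_radius(c, 0.37) * k == pytest.approx(1.0, rel=1e-12)

    def test_infinite_for_straight(self):
        assert g.osculating_radius(STRAIGHT, 0.5) == math.inf

    def test_circumcircle_oracle(self, rng):
        for _ in range(20):
            c = random_curve(rng)
            t = 0.45
            r = g.osculating_radius(c, t)
            hs = (1e-3, 5e-4)
            ests = []
            for h in hs:
                ests.append(
                    circumradius(
                        g.bezier_point(c, t - h), g.bezier_point(c, t), g.bezier_point(c, t + h)
                    )
                )
            # Richardson: error is O(h^2)
            extrap = ests[1] + (ests[1] - ests[0]) / 3.0
            assert extrap == pytest.approx(r, rel=1e-5)


class TestArcLength:
    def test_straight_unit(self):
        assert g.arc_length_numeric(STRAIGHT, 0, 1) == pytest.approx(1.0, abs=1e-10)

    def test_parabola_closed_form(self):
        assert g.arc_length_numeric(PARABOLA, 0, 1) == pytest.approx(PARABOLA_ARC, abs=1e-9)

    def test_additive(self, rng):
        c = random_curve(rng)
        tc = rng.uniform(0.1, 0.9)
        total = g.arc_length_numeric(c, 0, 1)
        split = g.arc_length_numeric(c, 0, tc) + g.arc_length_numeric(c, tc, 1)
        assert split == pytest.approx(total, abs=max(1e-9, 1e-9 * total))

    def test_arc_at_least_chord(self, rng):
        for _ in range(20):
            c = random_curve(rng)
            ta, tb = sorted(rng.uniform(0, 1, 2))
            chord = math.dist(g.bezier_point(c, ta), g.bezier_point(c, tb))
            assert g.arc_length_numeric(c, ta, tb) >= chord - 1e-9

    def test_reversed_interval_rejected(self):
        with pytest.raises(DomainError):
            g.arc_length_numeric(STRAIGHT, 0.7, 0.2)


class TestProfileArcs:
    def test_sup_arc_empty_and_full(self, fixture_landmarks):
        lm = fixture_landmarks
        assert g.sup_arc(lm, 0.0) == 0.0
        full = g.arc_length_numeric(g.upper_segment(lm), 0, 1)
        assert g.sup_arc(lm, 1.0) == pytest.approx(full, rel=1e-12)

    def test_inf_arc_empty_and_full(self, fixture_landmarks):
        lm = fixture_landmarks
        assert g.inf_arc(lm, 1.0) == 0.0
        full = g.arc_length_numeric(g.lower_segment(lm), 0, 1)
        assert g.inf_arc(lm, 0.0) == pytest.approx(full, rel=1e-12)

    def test_gl_oracle(self, rng):
        for _ in range(20):
            lm = random_profile_landmarks(rng)
            t1 = g.param_at_point(g.upper_segment(lm), lm.p1)
            t4 = g.param_at_point(g.lower_segment(lm), lm.p4)
            assert g.sup_arc(lm, t1) == pytest.approx(
                gl_arc_length(g.upper_segment(lm), 0, t1), rel=1e-9
            )
            assert g.inf_arc(lm, t4) == pytest.approx(
                gl_arc_length(g.lower_segment(lm), t4, 1), rel=1e-9
            )

    def test_total_arc_straight_chords(self):
        # both segments degenerate straight with chords 1 and 2 -> total 3
        y2 = 0.8 + math.sqrt(4 - 0.36)
        lm = ProfileLandmarks.from_raw(
            {
                "P0": (0.0, 0.0),
                "P3": (0.6, 0.8),
                "P5": (0.3, 0.4),
                "P6": (0.3, (0.8 + y2) / 2),
                "P2": (0.0, y2),
            },
            normalize=False,
        )
        assert g.total_arc(lm) == pytest.approx(3.0, abs=1e-9)

    def test_total_arc_at_least_sub_arcs(self, fixture_landmarks):
        lm = fixture_landmarks
        t1 = g.param_at_point(g.upper_segment(lm), lm.p1)
        t4 = g.param_at_point(g.lower_segment(lm), lm.p4)
        assert g.total_arc(lm) >= g.sup_arc(lm, t1) + g.inf_arc(lm, t4)

    def test_total_arc_polyline_oracle(self, rng):
        lm = random_profile_landmarks(rng)
        expect = polyline_length(g.upper_segment(lm)) + polyline_length(g.lower_segment(lm))
        assert g.total_arc(lm) == pytest.approx(expect, rel=1e-6)


def _lm_with(p1, p3, p2y=3.0, p4=None):
    """Hand-assembled landmarks for the area/volume formulas."""
    p4 = p4 or Point2D(0.5, p2y - 0.5)
    return ProfileLandmarks(
        p0=Point2D(0, 0),
        p1=Point2D(*p1),
        p2=Point2D(0, p2y),
        p3=Point2D(*p3),
        p4=p4,
        p5=Point2D(p1[0], p1[1] / 2),
        p6=Point2D(p3[0], (p3[1] + p2y) / 2),
        p8=Point2D(0, p1[1]),
    )


class TestAreaModel:
    def test_printed_example(self):
        lm = _lm_with((1, 1), (0, 2))
        coeffs = g.area_model(lm)
        assert coeffs.a == pytest.approx(-1.0, abs=1e-12)
        assert coeffs.b == pytest.approx(2.0, abs=1e-12)

    def test_interpolation_conditions(self, rng):
        for _ in range(50):
            x1, y1 = rng.uniform(0.5, 50), rng.uniform(1, 40)
            x3, y3 = rng.uniform(0.5, 50), rng.uniform(41, 90)
            lm = _lm_with((x1, y1), (x3, y3), p2y=100.0)
            c = g.area_model(lm)
            assert c.a * y1**2 + c.b * y1 == pytest.approx(x1, abs=1e-9 * max(1, x1))
            assert c.a * y3**2 + c.b * y3 == pytest.approx(x3, abs=1e-9 * max(1, x3))

    def test_linear_solve_oracle(self, rng):
        x1, y1, x3, y3 = 7.0, 13.0, 21.0, 55.0
        lm = _lm_with((x1, y1), (x3, y3), p2y=80.0)
        c = g.area_model(lm)
        m = np.array([[y1**2, y1], [y3**2, y3]])
        a, b = np.linalg.solve(m, [x1, x3])
        assert (c.a, c.b) == pytest.approx((a, b), rel=1e-12)

    def test_degenerate(self):
        lm = _lm_with((1, 2), (3, 2), p2y=5.0)  # y1 == y3
        with pytest.raises(DegenerateGeometryError):
            g.area_model(lm)


class TestArea1:
    def test_triangle(self):
        lm = _lm_with((2, 2), (1, 2.5), p2y=3.0)
        assert g.area1(lm, AreaModelCoefficients(0.0, 1.0)) == pytest.approx(2.0)

    def test_printed_example(self):
        lm = _lm_with((1, 1), (0, 2))
        assert g.area1(lm, AreaModelCoefficients(-1.0, 2.0)) == pytest.approx(2 / 3)

    def test_quadrature_oracle(self, rng):
        done = 0
        while done < 20:
            a, b = rng.uniform(-0.02, 0.02), rng.uniform(0.1, 2.0)
            y1 = rng.uniform(5.0, 60.0)
            if a * y1**2 + b * y1 <= 0.5:
                continue
            done += 1
            lm = _lm_with((a * y1**2 + b * y1, y1), (30, y1 + 20), p2y=y1 + 40)
            expect, _ = quad(lambda y: a * y * y + b * y, 0, y1, epsabs=1e-13)
            got = g.area1(lm, AreaModelCoefficients(a, b))
            assert got == pytest.approx(expect, rel=1e-10, abs=1e-10)


class TestTotalArea:
    def test_triangle_via_straight_segments(self):
        lm = ProfileLandmarks.from_raw(
            {
                "P0": (0.0, 0.0),
                "P5": (0.5, 0.5),
                "P3": (1.0, 1.0),
                "P6": (0.5, 1.5),
                "P2": (0.0, 2.0),
            },
            normalize=False,
        )
        assert g.total_area(lm) == pytest.approx(1.0, abs=1e-12)

    def test_shoelace_oracle(self, rng):
        lm = random_profile_landmarks(rng)
        expect = shoelace(dense_profile_polygon(lm))
        assert g.total_area(lm) == pytest.approx(expect, rel=1e-6)

    def test_rotation_invariance(self, rng):
        lm = random_profile_landmarks(rng)
        base = g.total_area(lm)
        th = math.radians(17.0)
        ca, sa = math.cos(th), math.sin(th)
        raw = {}
        for label in ("P0", "P2", "P3", "P5", "P6"):
            p = getattr(lm, label.lower())
            raw[label] = (ca * p.x - sa * p.y + 5.0, sa * p.x + ca * p.y - 3.0)
        lm2 = ProfileLandmarks.from_raw(raw)  # normalized back to canonical
        assert g.total_area(lm2) == pytest.approx(base, rel=1e-9)


class TestArea2:
    def test_complement(self, fixture_landmarks):
        assert g.area2(fixture_landmarks, 10.0, 4.0) == pytest.approx(6.0)

    def test_boundary_zero(self, fixture_landmarks):
        assert g.area2(fixture_landmarks, 5.0, 5.0) == 0.0

    def test_negative_warns(self, fixture_landmarks):
        with pytest.warns(UserWarning, match="area2"):
            g.area2(fixture_landmarks, 1.0, 2.0)

    def test_consistency_with_oracles(self, rng):
        # total via dense shoelace minus area1 via quadrature
        lm = random_profile_landmarks(rng)
        coeffs = g.area_model(lm)
        total = g.total_area(lm)
        a1 = g.area1(lm, coeffs)
        a1_q, _ = quad(lambda y: coeffs.a * y * y + coeffs.b * y, 0, lm.p1.y, epsabs=1e-12)
        expect = shoelace(dense_profile_polygon(lm)) - a1_q
        assert g.area2(lm, total, a1) == pytest.approx(expect, rel=1e-6)


class TestVlow:
    def test_cone(self):
        h = 3.7
        assert g.vlow_from_values(0.0, 1.0, 0.0, 0.0, h) == pytest.approx(
            math.pi * h**3 / 3.0, rel=1e-12
        )

    def test_degenerate_zero(self):
        assert g.vlow_from_values(0.0, 0.0, 1.0, 2.0, 5.0) == 0.0

    def test_quadrature_oracle(self, rng):
        for _ in range(20):
            a, b = rng.uniform(-0.01, 0.01), rng.uniform(0.1, 1.5)
            y1 = rng.uniform(1.0, 30.0)
            y2 = rng.uniform(1.0, 30.0)
            y4 = max(y1, y2) + rng.uniform(1.0, 30.0)
            got = g.vlow_from_values(a, b, y1, y2, y4)
            assert got == pytest.approx(g.vlow_quadrature(a, b, y1, y2, y4), rel=1e-10)

    def test_warns_when_p4_not_lowest(self, fixture_landmarks):
        lm = fixture_landmarks  # p4 above p2 here
        with pytest.warns(UserWarning, match="vlow"):
            g.vlow(lm, g.area_model(lm))


class TestProjections:
    def test_subtraction(self):
        lm = _lm_with((30, 40), (20, 60), p2y=100.0, p4=Point2D(50, 120))
        assert g.projections(lm) == pytest.approx((50.0, 20.0))

    def test_degenerate_minimum_at_p2(self):
        lm = _lm_with((30, 40), (20, 60), p2y=100.0, p4=Point2D(0, 100))
        assert g.projections(lm) == pytest.approx((0.0, 0.0))

    def test_ant_pr_is_x4_in_canonical_frame(self, fixture_landmarks):
        ant, _ = g.projections(fixture_landmarks)
        assert ant == fixture_landmarks.p4.x


class TestComputeMetrics:
    def test_all_fields_finite(self, fixture_landmarks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m = g.compute_metrics(fixture_landmarks)
        for name, value in m.as_dict().items():
            assert math.isfinite(value), name

    def test_determinism(self, fixture_landmarks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m1 = g.compute_metrics(fixture_landmarks)
            m2 = g.compute_metrics(fixture_landmarks)
        assert m1 == m2  # bitwise identical

    def test_rigid_motion_invariance(self, rng):
        lm = random_profile_landmarks(rng)
        raw = {}
        th = math.radians(31.0)
        ca, sa = math.cos(th), math.sin(th)
        for label in ("P0", "P1", "P2", "P3", "P4", "P5", "P6"):
            p = getattr(lm, label.lower())
            raw[label] = (ca * p.x - sa * p.y - 40.0, sa * p.x + ca * p.y + 17.0)
        lm2 = ProfileLandmarks.from_raw(raw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m1, m2 = g.compute_metrics(lm), g.compute_metrics(lm2)
        for name in ("k1", "k2", "sup_arc", "inf_arc", "total_arc", "total_area", "vlow"):
            assert getattr(m2, name) == pytest.approx(getattr(m1, name), rel=1e-9), name

    def test_invariants(self, rng):
        lm = random_profile_landmarks(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m = g.compute_metrics(lm)
        assert 0.0 <= m.t1 <= 1.0 and 0.0 <= m.t4 <= 1.0
        assert m.r1 * m.k1 == pytest.approx(1.0, rel=1e-12)
        assert m.r2 * m.k2 == pytest.approx(1.0, rel=1e-12)
        assert m.area1 + m.area2 == pytest.approx(m.total_area, rel=1e-9)
        chord_sup = math.dist(lm.p0, lm.p1)
        chord_inf = math.dist(lm.p4, lm.p2)
        assert m.sup_arc >= chord_sup - 1e-9
        assert m.inf_arc >= chord_inf - 1e-9


class TestPrintedClosedForms:
    def test_runs_and_reports_deviation(self, rng):
        # diagnostic path: the printed formulas are transcribed verbatim and
        # their (known, typo-driven) deviation from quadrature is reported
        devs = []
        for _ in range(20):
            lm = random_profile_landmarks(rng)
            t1 = g.param_at_point(g.upper_segment(lm), lm.p1)
            t4 = g.param_at_point(g.lower_segment(lm), lm.p4)
            sup_dev, inf_dev = g.closed_form_deviation(lm, t1, t4)
            for d in (sup_dev, inf_dev):
                assert math.isnan(d) or d >= 0.0
            devs.append((sup_dev, inf_dev))
        assert len(devs) == 20


class TestLandmarkValidation:
    def test_p0_off_origin_rejected(self):
        with pytest.raises(ValidationError):
            ProfileLandmarks(
                p0=Point2D(1, 0), p1=Point2D(1, 1), p2=Point2D(0, 3),
                p3=Point2D(1, 2), p4=Point2D(1, 2.5), p5=Point2D(1, 0.5),
                p6=Point2D(1, 2.6), p8=Point2D(0, 1),
            )

    def test_negative_x_rejected(self):
        with pytest.raises(ValidationError):
            ProfileLandmarks(
                p0=Point2D(0, 0), p1=Point2D(-5, 1), p2=Point2D(0, 3),
                p3=Point2D(1, 2), p4=Point2D(1, 2.5), p5=Point2D(1, 0.5),
                p6=Point2D(1, 2.6), p8=Point2D(0, 1),
            )

    def test_missing_required_raw_label(self):
        with pytest.raises(ValidationError, match="P3"):
            ProfileLandmarks.from_raw({"P0": (0, 0), "P2": (0, 10), "P5": (1, 1), "P6": (1, 8)})

    def test_normalization_idempotent(self, rng):
        lm = random_profile_landmarks(rng)
        raw = {
            label: tuple(getattr(lm, label.lower()))
            for label in ("P0", "P1", "P2", "P3", "P4", "P5", "P6")
        }
        lm2 = ProfileLandmarks.from_raw(raw)  # already canonical
        for label in ("p0", "p1", "p2", "p3", "p4", "p5", "p6", "p8"):
            a, b = getattr(lm, label), getattr(lm2, label)
            assert math.dist(a, b) <= 1e-12 * max(1.0, lm.p2.y)
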