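"""Quadratic-Bezier differential geometry of the two-segment torso profile curve.

The profile runs from the anterior axillary fold (P0) down to the iliac-crest
point (P2) and is modeled as two linked quadratic Bezier segments:

* upper segment: controls (P0, P5, P3),
* lower segment: controls (P3, P6, P2),

in a canonical frame with P0 at the origin, P2 on the positive y axis
(y grows downward along the body axis) and x pointing anteriorly.  P1 and P4
are the on-curve points of maximal x of the upper and lower segment; P8 is
the axis foot of P1.  From the landmarks we derive curvatures at P1/P4,
osculating radii, arc lengths, areas split at the waist plane y = y1, the
half volume of revolution of the axial parabola model, and the anterior /
inferior projections of P4.

Conventions adopted here (documented deviations from the printed source
formulas they mirror):

* Curvature is the standard unsigned plane-curve curvature
  ``|x'y'' - y'x''| / (x'^2 + y'^2)^{3/2}``.  The printed extremum-curvature
  expressions carry an inconsistent constant factor and are not used.
* Arc lengths are adaptive quadrature of the speed integral.  The printed
  closed forms are provided verbatim (``printed_sup_arc``/``printed_inf_arc``)
  for cross-checking only; their coefficient polynomials contain apparent
  typographical defects and must not be trusted blindly.
* ``area2 = total_area - area1`` so that ``area1 + area2 == total_area``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.integrate import quad

from .errors import DegenerateGeometryError, DomainError, NotOnCurveError, ValidationError

__all__ = [
    "Point2D",
    "QuadraticBezier",
    "ProfileLandmarks",
    "ArcLengthCoefficients",
    "AreaModelCoefficients",
    "ProfileMetrics",
    "bernstein",
    "bezier_point",
    "bezier_general",
    "decasteljau_split",
    "upper_segment",
    "lower_segment",
    "param_at_point",
    "t1_closed_form",
    "t4_closed_form",
    "curvature",
    "osculating_radius",
    "arc_length_numeric",
    "sup_arc",
    "inf_arc",
    "total_arc",
    "area_model",
    "area1",
    "total_area",
    "area2",
    "vlow",
    "vlow_from_values",
    "vlow_quadrature",
    "projections",
    "compute_metrics",
    "printed_sup_arc",
    "printed_inf_arc",
    "canonicalize_points",
]


class Point2D(NamedTuple):
    """A point in the profile plane (x anterior, y downward from P0)."""

    x: float
    y: float


@dataclass(frozen=True)
class QuadraticBezier:
    """Quadratic Bezier curve defined by three control points."""

    start: Point2D
    control: Point2D
    end: Point2D

    def __post_init__(self) -> None:
        for p in (self.start, self.control, self.end):
            if not (math.isfinite(p.x) and math.isfinite(p.y)):
                raise DomainError("control points must have finite coordinates")
        if self.start == self.end:
            raise DomainError("degenerate curve: start == end")

    # -- evaluation ---------------------------------------------------------
    def point(self, t: float) -> Point2D:
        return bezier_point(self, t)

    def derivative(self, t: float) -> Point2D:
        """First derivative B'(t) = 2[(1-t)(C-S) + t(E-C)]."""
        s, c, e = self.start, self.control, self.end
        return Point2D(
            2.0 * ((1.0 - t) * (c.x - s.x) + t * (e.x - c.x)),
            2.0 * ((1.0 - t) * (c.y - s.y) + t * (e.y - c.y)),
        )

    def second_derivative(self) -> Point2D:
        s, c, e = self.start, self.control, self.end
        return Point2D(2.0 * (e.x - 2.0 * c.x + s.x), 2.0 * (e.y - 2.0 * c.y + s.y))

    def speed(self, t: float) -> float:
        dx, dy = self.derivative(t)
        return math.hypot(dx, dy)

    def scale(self) -> float:
        """Bounding-box diagonal of the control polygon (tolerance yardstick)."""
        xs = (self.start.x, self.control.x, self.end.x)
        ys = (self.start.y, self.control.y, self.end.y)
        return math.hypot(max(xs) - min(xs), max(ys) - min(ys))


def bernstein(k: int, n: int, t: float) -> float:
    """Bernstein basis polynomial C(n,k) t^k (1-t)^(n-k) on [0, 1]."""
    if not (0 <= k <= n):
        raise DomainError(f"bernstein index k={k} outside 0..{n}")
    if not (0.0 <= t <= 1.0):
        raise DomainError(f"bernstein parameter t={t} outside [0, 1]")
    return math.comb(n, k) * t**k * (1.0 - t) ** (n - k)


def _check_t(t: float) -> None:
    if not (0.0 <= t <= 1.0):
        raise DomainError(f"curve parameter t={t} outside [0, 1]")


def bezier_point(curve: QuadraticBezier, t: float) -> Point2D:
    """Evaluate B(t) = (1-t)^2 S + 2t(1-t) C + t^2 E."""
    _check_t(t)
    u = 1.0 - t
    w0, w1, w2 = u * u, 2.0 * t * u, t * t
    s, c, e = curve.start, curve.control, curve.end
    return Point2D(w0 * s.x + w1 * c.x + w2 * e.x, w0 * s.y + w1 * c.y + w2 * e.y)


def bezier_general(controls: Sequence[Point2D], t: float) -> Point2D:
    """Degree-n Bezier point as the Bernstein-weighted control sum."""
    if len(controls) < 2:
        raise DomainError("a Bezier curve needs at least two control points")
    _check_t(t)
    n = len(controls) - 1
    x = y = 0.0
    for k, p in enumerate(controls):
        w = bernstein(k, n, t)
        x += w * p[0]
        y += w * p[1]
    return Point2D(x, y)


def decasteljau_split(curve: QuadraticBezier, t: float) -> tuple[QuadraticBezier, QuadraticBezier]:
    """Subdivide at t by de Casteljau; both halves retrace the original locus."""
    _check_t(t)

    def lerp(a: Point2D, b: Point2D) -> Point2D:
        return Point2D(a.x + t * (b.x - a.x), a.y + t * (b.y - a.y))

    q0 = lerp(curve.start, curve.control)
    q1 = lerp(curve.control, curve.end)
    m = lerp(q0, q1)
    return QuadraticBezier(curve.start, q0, m), QuadraticBezier(m, q1, curve.end)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

_REQUIRED_RAW = ("P0", "P2", "P3", "P5", "P6")


def canonicalize_points(points: Mapping[str, tuple[float, float]]) -> dict[str, Point2D]:
    """Rigidly move raw digitized points into the canonical frame.

    Translates P0 to the origin and rotates so P2 lies on the positive y
    axis.  If the bulk of the on-body points then has negative x the frame is
    mirrored so that x points anteriorly (digitizations may face either way).
    """
    missing = [k for k in ("P0", "P2") if k not in points]
    if missing:
        raise ValidationError(f"cannot normalize: missing {', '.join(missing)}")
    p0 = np.asarray(points["P0"], dtype=float)
    p2 = np.asarray(points["P2"], dtype=float)
    axis = p2 - p0
    d = float(np.hypot(*axis))
    if d == 0.0:
        raise DegenerateGeometryError("P0 and P2 coincide; no body axis")
    theta = math.atan2(axis[1], axis[0])
    alpha = math.pi / 2.0 - theta
    ca, sa = math.cos(alpha), math.sin(alpha)
    rot = np.array([[ca, -sa], [sa, ca]])

    out: dict[str, Point2D] = {}
    for label, xy in points.items():
        v = rot @ (np.asarray(xy, dtype=float) - p0)
        out[label] = Point2D(float(v[0]), float(v[1]))

    body = [out[k] for k in ("P1", "P3", "P4", "P5", "P6") if k in out]
    if body and sum(p.x for p in body) < 0.0:
        out = {k: Point2D(-p.x, p.y) for k, p in out.items()}

    # exact snap of the constrained coordinates
    out["P0"] = Point2D(0.0, 0.0)
    out["P2"] = Point2D(0.0, d)
    return out


def _x_extremum_t(seg: QuadraticBezier) -> float | None:
    """Parameter of an interior maximum of x(t) on a quadratic segment, or None."""
    s, c, e = seg.start.x, seg.control.x, seg.end.x
    acc = s - 2.0 * c + e          # x''(t)/2
    if acc == 0.0:
        return None
    t = (s - c) / acc
    if 0.0 < t < 1.0 and acc < 0.0:
        return t
    return None


@dataclass(frozen=True)
class ProfileLandmarks:
    """The nine named profile points in the canonical frame.

    ``p0=(0,0)``, ``p2=(0,y2)`` with ``y2>0``; ``p8=(0, p1.y)``; ``p7`` is
    retained for completeness but enters no formula.
    """

    p0: Point2D
    p1: Point2D
    p2: Point2D
    p3: Point2D
    p4: Point2D
    p5: Point2D
    p6: Point2D
    p8: Point2D
    p7: Point2D | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, atol: float = 1e-6) -> None:
        pts = [self.p0, self.p1, self.p2, self.p3, self.p4, self.p5, self.p6, self.p8]
        if self.p7 is not None:
            pts.append(self.p7)
        for p in pts:
            if not (math.isfinite(p.x) and math.isfinite(p.y)):
                raise ValidationError("landmark coordinates must be finite")
        scale = max(1.0, abs(self.p2.y))
        tol = atol * scale
        if abs(self.p0.x) > tol or abs(self.p0.y) > tol:
            raise ValidationError(f"P0 must sit at the origin, got {self.p0}")
        if abs(self.p2.x) > tol:
            raise ValidationError(f"P2 must lie on the y axis, got {self.p2}")
        if self.p2.y <= 0.0:
            raise ValidationError("P2 must lie strictly below P0 (y2 > 0)")
        for name in ("p1", "p3", "p4", "p5", "p6"):
            p = getattr(self, name)
            if p.x < -tol:
                raise ValidationError(f"{name.upper()} has negative x ({p.x})")
        if abs(self.p8.x) > tol or abs(self.p8.y - self.p1.y) > tol:
            raise ValidationError("P8 must equal (0, y1), the axis foot of P1")

    @classmethod
    def from_raw(
        cls,
        points: Mapping[str, tuple[float, float]],
        normalize: bool = True,
    ) -> "ProfileLandmarks":
        """Build landmarks from raw digitized coordinates.

        ``P0, P2, P3, P5, P6`` are required.  ``P1``/``P4`` are taken from the
        input when present, otherwise derived as the maximal-x on-curve points
        of the two segments (``P4`` falls back to ``P2`` when the lower
        segment has no interior extremum).  ``P8`` is always derived.
        """
        missing = [k for k in _REQUIRED_RAW if k not in points]
        if missing:
            raise ValidationError(f"missing required landmark(s): {', '.join(missing)}")
        pts = canonicalize_points(points) if normalize else {
            k: Point2D(float(v[0]), float(v[1])) for k, v in points.items()
        }
        upper = QuadraticBezier(pts["P0"], pts["P5"], pts["P3"])
        lower = QuadraticBezier(pts["P3"], pts["P6"], pts["P2"])
        if "P1" in pts:
            p1 = pts["P1"]
        else:
            t = _x_extremum_t(upper)
            p1 = bezier_point(upper, t) if t is not None else max(
                (upper.start, upper.end), key=lambda p: p.x
            )
        if "P4" in pts:
            p4 = pts["P4"]
        else:
            t = _x_extremum_t(lower)
            # degenerate minimum at P2: the profile can still be processed
            p4 = bezier_point(lower, t) if t is not None else pts["P2"]
        return cls(
            p0=pts["P0"],
            p1=p1,
            p2=pts["P2"],
            p3=pts["P3"],
            p4=p4,
            p5=pts["P5"],
            p6=pts["P6"],
            p8=Point2D(0.0, p1.y),
            p7=pts.get("P7"),
        )

    def scale(self) -> float:
        xs = [self.p1.x, self.p3.x, self.p4.x, self.p5.x, self.p6.x, 0.0]
        ys = [self.p1.y, self.p2.y, self.p3.y, self.p4.y, self.p5.y, self.p6.y, 0.0]
        return math.hypot(max(xs) - min(xs), max(ys) - min(ys))


def upper_segment(lm: ProfileLandmarks) -> QuadraticBezier:
    """Upper profile segment with controls (P0, P5, P3)."""
    return QuadraticBezier(lm.p0, lm.p5, lm.p3)


def lower_segment(lm: ProfileLandmarks) -> QuadraticBezier:
    """Lower profile segment with controls (P3, P6, P2)."""
    return QuadraticBezier(lm.p3, lm.p6, lm.p2)


# ---------------------------------------------------------------------------
# Parameter recovery, curvature, arc length
# ---------------------------------------------------------------------------

def param_at_point(
    curve: QuadraticBezier, pt: Point2D, rel_tol: float = 1e-6
) -> float:
    """Parameter t in [0,1] with B(t) == pt within tolerance.

    Minimizes |B(t) - pt|^2 exactly: the stationarity condition is a cubic in
    t whose real roots (plus the endpoints) are the only candidates.  The
    residual tolerance is ``rel_tol`` times the bounding-box diagonal.
    """
    s, c, e = curve.start, curve.control, curve.end
    ax, ay = s.x - 2 * c.x + e.x, s.y - 2 * c.y + e.y
    bx, by = 2 * (c.x - s.x), 2 * (c.y - s.y)
    cx, cy = s.x - pt.x, s.y - pt.y
    # d/dt |B-pt|^2 / 2 = sum over coords (a t^2 + b t + c)(2 a t + b)
    c3 = 2 * (ax * ax + ay * ay)
    c2 = 3 * (ax * bx + ay * by)
    c1 = bx * bx + by * by + 2 * (ax * cx + ay * cy)
    c0 = bx * cx + by * cy
    candidates = [0.0, 1.0]
    coeffs = [c3, c2, c1, c0]
    while coeffs and coeffs[0] == 0.0:
        coeffs = coeffs[1:]
    if len(coeffs) > 1:
        for r in np.roots(coeffs):
            if abs(r.imag) < 1e-9 and -1e-9 < r.real < 1.0 + 1e-9:
                candidates.append(min(1.0, max(0.0, float(r.real))))

    def dist(t: float) -> float:
        b = bezier_point(curve, t)
        return math.hypot(b.x - pt.x, b.y - pt.y)

    t_best = min(candidates, key=dist)
    scale = max(curve.scale(), math.hypot(pt.x - s.x, pt.y - s.y), 1e-300)
    if dist(t_best) > rel_tol * scale:
        raise NotOnCurveError(
            f"point {pt} is not on the curve (residual {dist(t_best):.3g} "
            f"> {rel_tol:.1g} x scale {scale:.3g})"
        )
    return t_best


def t1_closed_form(lm: ProfileLandmarks) -> float:
    """Closed-form parameter of P1 on the upper segment (cross-check only)."""
    x1, y1 = lm.p1
    x3, y3 = lm.p3
    x5, y5 = lm.p5
    den = 2.0 * (x5 * y3 - x3 * y5)
    if abs(den) < 1e-12 * max(1.0, lm.scale() ** 2):
        raise DegenerateGeometryError("t1 closed form: vanishing denominator")
    return (x1 * y3 - 2 * x1 * y5 + 2 * x5 * y1 - x3 * y1) / den


def t4_closed_form(lm: ProfileLandmarks) -> float:
    """Closed-form parameter of P4 on the lower segment (cross-check only)."""
    x3, y3 = lm.p3
    x4, y4 = lm.p4
    x6, y6 = lm.p6
    y2 = lm.p2.y
    den = 2.0 * (x6 * y2 - x6 * y3 - x3 * y2 + x3 * y6)
    if abs(den) < 1e-12 * max(1.0, lm.scale() ** 2):
        raise DegenerateGeometryError("t4 closed form: vanishing denominator")
    num = (
        x4 * y2 + x4 * y3 - 2 * x4 * y6 - x3 * y2 + 2 * x3 * y6
        + 2 * x6 * y4 - 2 * x6 * y3 - x3 * y4
    )
    return num / den


def curvature(curve: QuadraticBezier, t: float) -> float:
    """Unsigned curvature |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2) at t."""
    _check_t(t)
    dx, dy = curve.derivative(t)
    ddx, ddy = curve.second_derivative()
    speed_sq = dx * dx + dy * dy
    if speed_sq <= (1e-12 * max(curve.scale(), 1e-300)) ** 2:
        raise DegenerateGeometryError(f"vanishing speed at t={t}; curvature undefined")
    return abs(dx * ddy - dy * ddx) / speed_sq**1.5


def osculating_radius(curve: QuadraticBezier, t: float) -> float:
    """Reciprocal curvature; ``math.inf`` where the curve is locally straight."""
    k = curvature(curve, t)
    return math.inf if k == 0.0 else 1.0 / k


def arc_length_numeric(curve: QuadraticBezier, ta: float, tb: float) -> float:
    """Speed integral over [ta, tb] by adaptive quadrature (abs tol 1e-10)."""
    if not (0.0 <= ta <= tb <= 1.0):
        raise DomainError(f"need 0 <= ta <= tb <= 1, got ta={ta}, tb={tb}")
    if ta == tb:
        return 0.0
    val, _ = quad(curve.speed, ta, tb, epsabs=1e-10, epsrel=1e-12, limit=200)
    return val


def sup_arc(lm: ProfileLandmarks, t1: float) -> float:
    """Arc length P0->P1: upper segment over [0, t1]."""
    return arc_length_numeric(upper_segment(lm), 0.0, t1)


def inf_arc(lm: ProfileLandmarks, t4: float) -> float:
    """Arc length P4->P2: lower segment over [t4, 1]."""
    return arc_length_numeric(lower_segment(lm), t4, 1.0)


def total_arc(lm: ProfileLandmarks) -> float:
    """Full length of both segments (includes the P1->P3->P4 mid-portion)."""
    return arc_length_numeric(upper_segment(lm), 0.0, 1.0) + arc_length_numeric(
        lower_segment(lm), 0.0, 1.0
    )


# ---------------------------------------------------------------------------
# Printed arc-length closed forms (verbatim, cross-check only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArcLengthCoefficients:
    """Coefficients of one printed arc-length closed form (verbatim)."""

    a: float
    b: float
    c: float
    d: float = math.nan        # upper-limit shift (superior form)
    dprime: float = math.nan   # lower-limit shift (inferior form)
    e: float = math.nan
    ksq: float = math.nan
    delta: float = math.nan
    deltaprime: float = math.nan


def _safe_sqrt(v: float) -> float:
    return math.sqrt(v) if v >= 0.0 else math.nan


def _safe_log(v: float) -> float:
    return math.log(v) if v > 0.0 else math.nan


def printed_sup_arc(lm: ProfileLandmarks, t1: float) -> tuple[float, ArcLengthCoefficients]:
    """The printed superior arc-length closed form, transcribed verbatim.

    Known to disagree with quadrature for general landmarks (its ``b``
    coefficient and discriminant polynomial contain apparent typos); returns
    NaN when an intermediate leaves the real domain.
    """
    x3, y3 = lm.p3
    x5, y5 = lm.p5
    a = x3**2 - 4 * x3 * x5 + 4 * x5**2 + y3**2 - 4 * y3 * y5 + 4 * y5**2
    b = 2 * (3 * x3 * x5 + y3 * y5 - 2 * x5**2 - 2 * y5**2)
    c = x5**2 + y5**2
    delta = (
        -3 * x3**2 * x5**2 - 3 * y3**2 * y5**2 - 12 * x5**4 - 12 * y5**4
        + 2 * x3 * x5 * y3 * y5 + 12 * x3 * x5**3 + 12 * x3 * x5 * y3 * y5**2
        + 12 * x5**2 * y3 * y5 + 12 * y3 * y5**3 - 24 * x5**2 * y5**2
        - 4 * x5**2 * y3**2 - 4 * x3**2 * y5**2
    )
    if a <= 0.0:
        return math.nan, ArcLengthCoefficients(a, b, c, delta=delta)
    d = t1 + b / (2 * a)
    e = b / (2 * a)
    ksq = -delta / (4 * a)
    val = math.sqrt(a) * (
        d * _safe_sqrt(d * d + ksq)
        - e * _safe_sqrt(e * e + ksq)
        + ksq * _safe_log(d + _safe_sqrt(d * d + ksq))
        - ksq * _safe_log(e + _safe_sqrt(e * e + ksq))
    )
    return val, ArcLengthCoefficients(a, b, c, d=d, e=e, ksq=ksq, delta=delta)


def printed_inf_arc(lm: ProfileLandmarks, t4: float) -> tuple[float, ArcLengthCoefficients]:
    """The printed inferior arc-length closed form, transcribed verbatim.

    The discriminant polynomial as printed contains both ``-12 x3 x6^3`` and
    ``+12 x3 x6^3`` terms (kept; they cancel) and the ``c`` coefficient lacks
    the ``y3^2 + y6^2`` terms a derivation produces.  Cross-check only.
    """
    x3, y3 = lm.p3
    x6, y6 = lm.p6
    y2 = lm.p2.y
    a = (
        x3**2 + 4 * x6**2 - 4 * x3 * x6 + y3**2 + y2**2 + 4 * y6**2
        + 2 * y2 * y3 - 4 * y3 * y6 - 4 * y2 * y6
    )
    b = 2 * (
        3 * x3 * x6 + 3 * y3 * y6 - 2 * x6**2 - 2 * y6**2 - x3**2 - y3**2
        + y2 * y6 - y2 * y3
    )
    c = x6**2 + x3**2 - 2 * x3 * x6 - 2 * y3 * y6
    deltap = (
        y3**2 * y6**2 + 4 * y6**4 + y3**4 + y2**2 * y6**2 + y2**2 * y3**2
        + 2 * x3 * x6 * y3 * y6 - 12 * x3 * x6**3 - 4 * x3 * x6 * y6**2
        - 4 * x3 * x6 * y3**2 - 2 * x3 * x6 * y2 * y6 - x3 * x6 * y2 * y3
        - 4 * y3 * y6**3 - 4 * y3**3 * y6 + 2 * y2 * y3 * y6**2
        - 4 * y2 * y3**2 * y6 + 4 * x6**2 * y6**2 + 3 * x6**2 * y3**2
        + 2 * x6**2 * y2 * y3 - 4 * y2 * y6**3 + x3**2 * y3**2
        + 2 * x3**2 * y2 * y6 + 2 * y2 * y3**3 + 12 * x3 * x6**3
        - x6**2 * y2**2 - x3**2 * y2**2 + 2 * x3 * x6 * y2**2
    )
    if a <= 0.0:
        return math.nan, ArcLengthCoefficients(a, b, c, deltaprime=deltap)
    e = 1.0 + b / (2 * a)
    dp = t4 + b / (2 * a)
    ksq = -deltap / (a * a)
    val = math.sqrt(a) * (
        e * _safe_sqrt(e * e + ksq)
        - dp * _safe_sqrt(dp * dp + ksq)
        + ksq * _safe_log(e + _safe_sqrt(e * e + ksq))
        - ksq * _safe_log(dp + _safe_sqrt(dp * dp + ksq))
    )
    return val, ArcLengthCoefficients(a, b, c, dprime=dp, e=e, ksq=ksq, deltaprime=deltap)


def closed_form_deviation(lm: ProfileLandmarks, t1: float, t4: float) -> tuple[float, float]:
    """Relative deviation of the printed closed forms from quadrature.

    Returns ``(sup_dev, inf_dev)``; NaN where the printed form leaves the
    real domain.  Purely diagnostic.
    """
    sup_q = sup_arc(lm, t1)
    inf_q = inf_arc(lm, t4)
    sup_c, _ = printed_sup_arc(lm, t1)
    inf_c, _ = printed_inf_arc(lm, t4)
    dev = lambda c, q: abs(c - q) / abs(q) if q != 0.0 else abs(c - q)
    return dev(sup_c, sup_q), dev(inf_c, inf_q)


# ---------------------------------------------------------------------------
# Areas and the axial parabola model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaModelCoefficients:
    """Coefficients of the axial parabola x(y) = a y^2 + b y through P0, P1, P3."""

    a: float
    b: float


def area_model(lm: ProfileLandmarks) -> AreaModelCoefficients:
    """Fit the axial parabola x(y) = a y^2 + b y through (x1,y1) and (x3,y3)."""
    x1, y1 = lm.p1
    x3, y3 = lm.p3
    if y1 == 0.0 or y3 == 0.0 or y1 == y3:
        raise DegenerateGeometryError(
            "area model needs distinct non-zero y1, y3 "
            f"(got y1={y1}, y3={y3})"
        )
    a = (x3 * y1 - x1 * y3) / (y1 * y3**2 - y1**2 * y3)
    b = x3 / y3 - a * y3
    scale = max(abs(x1), abs(x3), 1.0)
    for xv, yv in ((x1, y1), (x3, y3)):
        if abs(a * yv**2 + b * yv - xv) > 1e-9 * scale:
            # interpolation takes precedence over the printed expression
            m = np.array([[y1**2, y1], [y3**2, y3]], dtype=float)
            a, b = np.linalg.solve(m, np.array([x1, x3], dtype=float))
            break
    return AreaModelCoefficients(float(a), float(b))


def area1(lm: ProfileLandmarks, coeffs: AreaModelCoefficients) -> float:
    """Area between the axial parabola and the body axis for y in [0, y1]."""
    y1 = lm.p1.y
    return coeffs.a * y1**3 / 3.0 + coeffs.b * y1**2 / 2.0


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(4)
_GL_T = 0.5 * (_GL_NODES + 1.0)


def _green_segment(seg: QuadraticBezier) -> float:
    """Exact integral of (x y' - y x') dt over a quadratic segment (cubic integrand)."""
    total = 0.0
    for t, w in zip(_GL_T, _GL_WEIGHTS):
        x, y = bezier_point(seg, t)
        dx, dy = seg.derivative(t)
        total += w * (x * dy - y * dx)
    return 0.5 * total  # dt scaling from [-1,1] to [0,1]


def total_area(lm: ProfileLandmarks, check_simple: bool = True) -> float:
    """Area enclosed by the two segments and the axis closure P2->P0.

    Green's theorem line integral 0.5 * integral(x dy - y dx); the straight
    closure along x = 0 contributes nothing.  Returned positive.
    """
    if check_simple:
        ts = np.linspace(0.0, 1.0, 64)
        up, lo = upper_segment(lm), lower_segment(lm)
        pts = [bezier_point(up, t) for t in ts] + [bezier_point(lo, t) for t in ts[1:]]
        try:
            from shapely.geometry import Polygon

            if not Polygon(pts).is_valid:
                warnings.warn("profile contour self-intersects; area taken as absolute value")
        except ImportError:  # pragma: no cover - shapely is an optional check
            pass
    signed = 0.5 * (_green_segment(upper_segment(lm)) + _green_segment(lower_segment(lm)))
    return abs(signed)


def area2(lm: ProfileLandmarks, total: float, a1: float) -> float:
    """Area below the waist plane: total enclosed area minus area1."""
    res = total - a1
    if res < 0.0:
        warnings.warn(
            f"area2 = {res:.4g} < 0: landmarks inconsistent with the waist-plane split"
        )
    return res


# ---------------------------------------------------------------------------
# Lower-belly half volume of revolution
# ---------------------------------------------------------------------------

def _vol_antiderivative(a: float, b: float, y: float) -> float:
    """F(y) = integral of (a y^2 + b y)^2 dy = a^2 y^5/5 + a b y^4/2 + b^2 y^3/3."""
    return a * a * y**5 / 5.0 + a * b * y**4 / 2.0 + b * b * y**3 / 3.0


def vlow_from_values(a: float, b: float, y1: float, y2: float, y4: float) -> float:
    """Half volume of revolution of the axial parabola, printed combination.

    Equals (pi/2) * [2 F(y4) - F(y1) - F(y2)] with F the antiderivative of
    x(y)^2; the half factor models anterior-only belly development.
    """
    return (math.pi / 2.0) * (
        2 * a**2 / 5.0 * y4**5 + a * b * y4**4 + 2 * b**2 / 3.0 * y4**3
        - a**2 / 5.0 * y1**5 - a * b / 2.0 * y1**4 - b**2 / 3.0 * y1**3
        - a**2 / 5.0 * y2**5 - a * b / 2.0 * y2**4 - b**2 / 3.0 * y2**3
    )


def vlow(lm: ProfileLandmarks, coeffs: AreaModelCoefficients) -> float:
    """Lower-belly half volume for a landmark set (warns if P4 is not lowest)."""
    y1, y2, y4 = lm.p1.y, lm.p2.y, lm.p4.y
    if not (y4 > y1 and y4 > y2):
        warnings.warn(
            f"vlow expects y4 below y1 and y2 (got y1={y1:.4g}, y2={y2:.4g}, y4={y4:.4g})"
        )
    return vlow_from_values(coeffs.a, coeffs.b, y1, y2, y4)


def vlow_quadrature(a: float, b: float, y1: float, y2: float, y4: float) -> float:
    """Numeric companion: (pi/2) * (int_{y1}^{y4} + int_{y2}^{y4}) x(y)^2 dy."""
    f = lambda y: (a * y**2 + b * y) ** 2
    v1, _ = quad(f, y1, y4, epsabs=1e-12, epsrel=1e-12)
    v2, _ = quad(f, y2, y4, epsabs=1e-12, epsrel=1e-12)
    return (math.pi / 2.0) * (v1 + v2)


def projections(lm: ProfileLandmarks) -> tuple[float, float]:
    """Anterior (x4 - x2) and inferior (y4 - y2) projections of P4."""
    return lm.p4.x - lm.p2.x, lm.p4.y - lm.p2.y


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileMetrics:
    """Derived geometric parameter vector of one profile."""

    t1: float
    t4: float
    k1: float
    k2: float
    r1: float
    r2: float
    sup_arc: float
    inf_arc: float
    total_arc: float
    area1: float
    area2: float
    total_area: float
    vlow: float
    ant_pr: float
    inf_pr: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_metrics(lm: ProfileLandmarks, check_simple: bool = True) -> ProfileMetrics:
    """Compute every profile metric; failures name the offending parameter."""
    up, lo = upper_segment(lm), lower_segment(lm)
    out: dict[str, float] = {}

    def step(name: str, fn):
        try:
            out[name] = fn()
        except Exception as exc:
            raise DegenerateGeometryError(f"failed computing {name}: {exc}") from exc

    step("t1", lambda: param_at_point(up, lm.p1))
    step("t4", lambda: param_at_point(lo, lm.p4))
    step("k1", lambda: curvature(up, out["t1"]))
    step("k2", lambda: curvature(lo, out["t4"]))
    step("r1", lambda: osculating_radius(up, out["t1"]))
    step("r2", lambda: osculating_radius(lo, out["t4"]))
    step("sup_arc", lambda: sup_arc(lm, out["t1"]))
    step("inf_arc", lambda: inf_arc(lm, out["t4"]))
    step("total_arc", lambda: total_arc(lm))
    coeffs = area_model(lm)
    step("area1", lambda: area1(lm, coeffs))
    step("total_area", lambda: total_area(lm, check_simple=check_simple))
    step("area2", lambda: area2(lm, out["total_area"], out["area1"]))
    step("vlow", lambda: vlow(lm, coeffs))
    ant, inf_ = projections(lm)
    out["ant_pr"], out["inf_pr"] = ant, inf_
    return ProfileMetrics(**out)
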