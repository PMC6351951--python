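"""Independent brute-force oracles used by the test suite.

Deliberately simple re-implementations (finite differences, dense polylines,
fixed-order Gauss-Legendre, straight-line interval logic) kept separate from
the package so that every closed-form path is checked against a second route.
"""

from __future__ import annotations

import math

import numpy as np

from abdoprofile.geometry import QuadraticBezier, bezier_point


def fd_curvature(curve: QuadraticBezier, t: float, h: float = 1e-3) -> float:
    """Curvature from central finite differences on sampled points.

    Central differences are exact for quadratic coordinates at any step, so
    the step only controls floating-point cancellation; 1e-3 keeps the
    roundoff comfortably below 1e-6 relative (1e-5 does not, in binary64).
    """
    pm = bezier_point(curve, t - h)
    p0 = bezier_point(curve, t)
    pp = bezier_point(curve, t + h)
    dx = (pp.x - pm.x) / (2 * h)
    dy = (pp.y - pm.y) / (2 * h)
    ddx = (pp.x - 2 * p0.x + pm.x) / h**2
    ddy = (pp.y - 2 * p0.y + pm.y) / h**2
    return abs(dx * ddy - dy * ddx) / (dx * dx + dy * dy) ** 1.5


def circumradius(p1, p2, p3) -> float:
    """Radius of the circle through three points."""
    a = math.dist(p1, p2)
    b = math.dist(p2, p3)
    c = math.dist(p1, p3)
    area2 = abs(
        (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p3[0] - p1[0]) * (p2[1] - p1[1])
    )
    if area2 == 0.0:
        return math.inf
    return a * b * c / (2.0 * area2)


_GL64_X, _GL64_W = np.polynomial.legendre.leggauss(64)


def gl_arc_length(curve: QuadraticBezier, ta: float, tb: float) -> float:
    """Fixed-order (n=64) Gauss-Legendre value of the speed integral."""
    mid, half = 0.5 * (ta + tb), 0.5 * (tb - ta)
    ts = mid + half * _GL64_X
    return half * sum(w * curve.speed(t) for t, w in zip(ts, _GL64_W))


def polyline_length(curve: QuadraticBezier, n: int = 100_000) -> float:
    ts = np.linspace(0.0, 1.0, n + 1)
    pts = np.array([bezier_point(curve, t) for t in ts])
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def dense_profile_polygon(lm, n: int = 50_000) -> np.ndarray:
    from abdoprofile.geometry import lower_segment, upper_segment

    ts = np.linspace(0.0, 1.0, n)
    up, lo = upper_segment(lm), lower_segment(lm)
    pts = [bezier_point(up, t) for t in ts] + [bezier_point(lo, t) for t in ts[1:]]
    return np.array(pts)


def conic_fit_residual(points: np.ndarray) -> tuple[float, float]:
    """Best implicit conic through the points (coords normalized to [0,1]).

    Returns (max |q(x,y)| residual, |B^2 - 4AC| discriminant magnitude) for
    the unit-norm coefficient vector of A x^2 + B xy + C y^2 + D x + E y + F.
    """
    lo = points.min(axis=0)
    span = np.maximum(points.max(axis=0) - lo, 1e-12)
    p = (points - lo) / span
    x, y = p[:, 0], p[:, 1]
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    coef = vt[-1]
    resid = float(np.max(np.abs(design @ coef)))
    a, b, c = coef[0], coef[1], coef[2]
    return resid, abs(b * b - 4 * a * c)


# ---------------------------------------------------------------------------
# Straight-line classification re-implementation
# ---------------------------------------------------------------------------

def brute_force_classify(k2, inf_arc, k1, area2, ant_pr, inf_pr):
    """Literal transcription of the interval tables, no shared code."""
    if 0.000493763 <= k2 <= 0.027066286 and 108.0939 <= inf_arc <= 214.7204:
        c1 = "RP"
    elif 0.029424926 <= k2 <= 0.080514181 and 225.8813 <= inf_arc <= 391.5648:
        c1 = "FP"
    else:
        c1 = "indeterminate"

    ftp = 0.000194215 <= k1 <= 0.005002445 and 7.56 <= area2 <= 94.89
    pp = 0.006819941 <= k1 <= 0.014204314 and 91.35 <= area2 <= 187.54
    if ftp and not pp:
        c2 = "FTP"
    elif pp and not ftp:
        c2 = "PP"
    else:
        c2 = "indeterminate"

    if ant_pr < 22.39 or ant_pr > 115.9:
        ant = "out_of_range"
    elif ant_pr < 69.16:
        ant = "below_average"
    else:
        ant = "above_average"
    if inf_pr < 2.41 or inf_pr > 108.88:
        inf_ = "out_of_range"
    elif inf_pr < 42.85:
        inf_ = "below_average"
    else:
        inf_ = "above_average"

    if c2 == "PP" and ant == "above_average":
        ta = "steatosic"
    elif c2 == "FTP" and ant == "below_average":
        ta = "non_steatosic"
    else:
        ta = "indeterminate"
    if c1 == "FP" and inf_ == "above_average":
        tb = "steatosic"
    elif c1 == "RP" and inf_ == "below_average":
        tb = "non_steatosic"
    else:
        tb = "indeterminate"
    return c1, c2, ant, inf_, ta, tb
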