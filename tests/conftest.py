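import numpy as np
import pytest

from abdoprofile.geometry import Point2D, ProfileLandmarks, QuadraticBezier


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fixture_landmarks() -> ProfileLandmarks:
    """A deterministic, well-behaved profile (upper and lower bulges)."""
    return ProfileLandmarks.from_raw(
        {
            "P0": (0.0, 0.0),
            "P5": (60.0, 30.0),
            "P3": (40.0, 70.0),
            "P6": (55.0, 160.0),
            "P2": (0.0, 220.0),
        },
        normalize=False,
    )


def random_profile_landmarks(rng: np.random.Generator) -> ProfileLandmarks:
    """A random non-degenerate landmark set with interior extrema on both segments."""
    x3 = rng.uniform(10.0, 50.0)
    y3 = rng.uniform(40.0, 100.0)
    y2 = y3 + rng.uniform(80.0, 250.0)
    raw = {
        "P0": (0.0, 0.0),
        "P2": (0.0, y2),
        "P3": (x3, y3),
        "P5": (x3 + rng.uniform(5.0, 40.0), rng.uniform(0.25, 0.75) * y3),
        "P6": (x3 + rng.uniform(5.0, 80.0), y3 + rng.uniform(0.3, 1.1) * (y2 - y3)),
    }
    return ProfileLandmarks.from_raw(raw, normalize=False)


def random_curve(rng: np.random.Generator, box: float = 300.0) -> QuadraticBezier:
    """A random non-degenerate quadratic Bezier with coordinates in [0, box]."""
    while True:
        pts = rng.uniform(0.0, box, size=(3, 2))
        s, c, e = (Point2D(*p) for p in pts)
        if (s.x, s.y) != (e.x, e.y):
            # also avoid zero-speed endpoints (control coincident with an end)
            if (s.x, s.y) != (c.x, c.y) and (e.x, e.y) != (c.x, c.y):
                return QuadraticBezier(s, c, e)
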