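"""Exception hierarchy shared by all abdoprofile modules."""


class ProfileError(Exception):
    """Base class for all abdoprofile errors."""


class DomainError(ProfileError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class NotOnCurveError(DomainError):
    """A point claimed to lie on a curve has a residual above tolerance."""


class DegenerateGeometryError(DomainError):
    """Landmark geometry collapses a formula (zero speed, coincident points...)."""


class ValidationError(ProfileError, ValueError):
    """Structured input (tables, landmark sets) violates its contract."""


class ParseError(ProfileError, ValueError):
    """Malformed text input; carries a line number where available."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedPathError(ProfileError, ValueError):
    """SVG path not in the supported two-quadratic-segment dialect."""


class GenerationInfeasibleError(ProfileError, RuntimeError):
    """Rejection sampling failed to produce a profile of the requested class."""


class CollinearityError(DomainError):
    """Rank-deficient control matrix in a partial-correlation adjustment."""
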