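"""Exception hierarchy shared across the package."""


class TriadetError(Exception):
    """Base class for all triadet errors."""


class InputError(TriadetError, ValueError):
    """Invalid user input (unknown ids, bad shapes, violated preconditions)."""


class PoleError(TriadetError, ValueError):
    """Tunnelling energy coincides with a bridge eigenvalue."""

    def __init__(self, message: str, eigenvalue: float | None = None):
        super().__init__(message)
        self.eigenvalue = eigenvalue


class ConvergenceError(TriadetError, RuntimeError):
    """Self-consistent iteration failed to converge; carries the trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


class FitError(TriadetError, RuntimeError):
    """A least-squares fit failed on every start."""


class FormatError(TriadetError, ValueError):
    """A structured file could not be parsed."""


class GeometryError(TriadetError, ValueError):
    """Degenerate geometry (e.g. coincident atoms in an angle)."""
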