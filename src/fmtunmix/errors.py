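"""Exception hierarchy.

Errors are grouped by origin: geometry/mesh problems, configuration and
I/O problems, and algorithmic failures of the separation engine.  The CLI
maps the first two groups to exit code 1 and the last to exit code 2.
"""


class FmtUnmixError(Exception):
    """Base class for all package errors."""


# --- geometry / forward model ------------------------------------------------

class InvalidGeometryError(FmtUnmixError):
    """Nonpositive or inconsistent mesh/phantom dimensions."""


class MeshQualityError(FmtUnmixError):
    """Degenerate element (near-zero area) encountered during assembly."""


class SolverFailureError(FmtUnmixError):
    """The sparse linear solve failed or produced an unacceptable residual."""


class InvalidDetectorError(FmtUnmixError):
    """A requested detector node is not on the mesh boundary."""


class InvalidParameterError(FmtUnmixError):
    """A physical parameter is out of its admissible range."""


class RasterizationError(FmtUnmixError):
    """An inclusion covers no mesh node at the current resolution."""


# --- stacks / scenes ---------------------------------------------------------

class ShapeMismatchError(FmtUnmixError):
    """Array shapes of frames/patterns/courses are inconsistent."""


class AlreadySubtractedError(FmtUnmixError):
    """Background subtraction requested on an already-subtracted stack."""


class EmptyFrameError(FmtUnmixError):
    """A frame has nonpositive total intensity and cannot be sum-normalized."""


# --- unmixing ----------------------------------------------------------------

class InsufficientFramesError(FmtUnmixError):
    """Fewer than two frames: no temporal structure to analyse."""


class DimensionError(FmtUnmixError):
    """Requested source count exceeds the number of frames."""


class DegenerateStackError(FmtUnmixError):
    """Centered frame matrix has lower rank than the requested model order."""


class InfeasibleGeometryError(FmtUnmixError):
    """The observation polyhedron is numerically empty or unbounded."""


class NonIdentifiableError(FmtUnmixError):
    """Could not find the requested number of distinct extreme points."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UndefinedCorrelationError(FmtUnmixError):
    """Correlation requested against a constant vector."""


# --- configuration / CLI -----------------------------------------------------

class ConfigValidationError(FmtUnmixError):
    """Scene/run configuration is invalid; carries the offending keys."""

    def __init__(self, message, keys=()):
        super().__init__(message)
        self.keys = tuple(keys)
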