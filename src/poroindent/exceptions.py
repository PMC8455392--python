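"""Package-specific error types."""


class PoroindentError(Exception):
    """Base class for all package errors."""


class DegenerateDeformationError(PoroindentError):
    """Deformation state with non-positive volumetric Jacobian."""


class MeshError(PoroindentError):
    """Mesh construction failed (invalid geometry or resolution)."""


class ProtocolError(PoroindentError):
    """Loading protocol is inconsistent or physically unreachable."""


class ConvergenceError(PoroindentError):
    """Newton iteration failed to converge; carries step diagnostics."""

    def __init__(self, message, time=None, step=None):
        super().__init__(message)
        self.time = time
        self.step = step


class SignalQualityError(PoroindentError):
    """Drive frequency not resolvable in a dynamic record."""


class RangeError(PoroindentError):
    """Argument outside the solvable/tabulated range."""
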