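"""Exception types shared across the package."""


class FormantCompError(Exception):
    """Base class for all package-specific errors."""


class InvalidTrackError(FormantCompError, ValueError):
    """A formant track violates its invariants (empty, non-positive, mismatched)."""


class SeparationViolationError(FormantCompError, RuntimeError):
    """A competitor contour approaches F1 closer than the minimum separation.

    Attributes
    ----------
    violations : list of int
        Frame indices at which the constraint is violated.
    worst_frame : int
        Index of the frame with the smallest separation.
    worst_gap_hz : float
        The separation at ``worst_frame``.
    """

    def __init__(self, message: str, violations, worst_frame: int, worst_gap_hz: float):
        super().__init__(message)
        self.violations = list(violations)
        self.worst_frame = worst_frame
        self.worst_gap_hz = worst_gap_hz
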