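"""Exception hierarchy.

All package-specific failures derive from :class:`CiliabeatError` so callers
can catch one base class; the CLI maps validation-type errors to exit code 2
and cross-file consistency errors to exit code 3.
"""


class CiliabeatError(Exception):
    """Base class for all ciliabeat errors."""


class InvalidAnnotationError(CiliabeatError):
    """A beat-cycle annotation violates its invariants (ordering, finiteness)."""


class DegenerateGeometryError(CiliabeatError):
    """Landmark geometry is degenerate (e.g. zero-length arm for the beat angle)."""


class InvalidScoreError(CiliabeatError):
    """A beating score or weighting fraction is outside its allowed set/range."""


class InvalidLabelError(CiliabeatError):
    """An unknown beat-pattern label was encountered."""


class InsufficientDataError(CiliabeatError):
    """Too few observations to compute the requested statistic."""


class UndefinedRateError(CiliabeatError):
    """Sensitivity/specificity undefined because one class is absent."""


class ConfigurationError(CiliabeatError):
    """Invalid run or model configuration (e.g. inverted cutoffs)."""


class GeometryError(CiliabeatError):
    """Simulated object does not fit the requested field of view."""


class TrackingFailureError(CiliabeatError):
    """Tip tracking failed on some frame (empty foreground)."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class ParseError(CiliabeatError):
    """A data file row failed validation; carries row/field context."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        super().__init__(message)
        self.row = row
        self.field = field


class ConsistencyError(CiliabeatError):
    """Patient identifiers disagree across input files."""

    def __init__(self, message: str, orphans: list | None = None):
        super().__init__(message)
        self.orphans = orphans or []
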