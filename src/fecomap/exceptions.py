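"""Exception hierarchy for fecomap.

``FecomapError`` is the common base; ``InvalidParameterError`` covers bad
configuration values, ``DataError`` covers problems with the data itself
(too-short traces, empty masks, inconsistent trial tables, ...).
"""


class FecomapError(Exception):
    """Base class for all fecomap errors."""


class InvalidParameterError(FecomapError, ValueError):
    """A parameter value violates a documented precondition."""


class DataError(FecomapError, ValueError):
    """Input data violates a documented precondition."""


class RoiLayoutError(DataError):
    """ROIs overlap or fall outside the frame."""


class RenderError(DataError):
    """A synthetic scene cannot be rendered (e.g. the pin exits the frame)."""


class DegenerateBaselineError(DataError):
    """The computed fluorescence baseline is not strictly positive."""


class TraceTooShortError(DataError):
    """A trace does not cover the requested analysis window."""


class UndefinedKineticsError(DataError):
    """Kinetics are requested for a trace with non-positive peak."""


class NoPinDetectedError(DataError):
    """Thresholding a leg-video frame produced an empty mask."""


class OrientationUndefinedError(DataError):
    """The second-moment matrix is isotropic; the long axis is undefined."""


class MissingDataError(DataError):
    """A required (fly, condition) combination is absent from a table."""
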