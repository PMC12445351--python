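"""Exception hierarchy.

Everything raised on bad user input derives from :class:`KScoreError` so callers
can distinguish data problems from programming errors.
"""


class KScoreError(Exception):
    """Base class for all package errors."""


class SchemaError(KScoreError):
    """Input table is missing required columns or has an unknown layout."""


class DataValidationError(KScoreError):
    """Input parsed but violates a contract (non-monotone time, NaNs, ...)."""


class ParameterError(KScoreError):
    """A configuration or function parameter is out of its valid range."""


class SegmentationError(KScoreError):
    """Sit-to-stand repetitions could not be extracted from a recording."""


class StaticRecordingError(SegmentationError):
    """The segmentation signal shows no usable vertical displacement."""


class ConvergenceError(KScoreError):
    """An iterative procedure (GPA) failed to converge."""
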