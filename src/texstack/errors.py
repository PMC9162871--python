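"""Exception hierarchy.

``TexstackError`` is the base; user-facing code (the CLI) maps
``ParameterError`` to exit code 1 and ``DataError`` subclasses to 2.
"""


class TexstackError(Exception):
    """Base class for all package errors."""


class ParameterError(TexstackError, ValueError):
    """An argument violates a documented precondition."""


class DataError(TexstackError):
    """Input data violates a contract (missing files, degenerate content)."""


class DegenerateRoiError(DataError):
    """An ROI has no usable variation (e.g. constant intensities)."""


class RegistrationError(DataError):
    """Moving and reference grids share no physical extent."""


class AlignmentError(DataError):
    """Per-patient score vectors do not line up across models."""


class MetricError(DataError):
    """A metric is undefined for the given labels (e.g. one class only)."""
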