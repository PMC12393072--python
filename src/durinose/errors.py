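"""Exception hierarchy for the durinose pipeline.

Every stage raises a subclass of :class:`DurinoseError` so the CLI can
abort with the failing stage's name and context attached.
"""


class DurinoseError(Exception):
    """Base class for all durinose errors."""


class ValidationError(DurinoseError):
    """A configuration value or input label is outside its contract."""


class SchemaError(DurinoseError):
    """A CSV is missing required columns or has the wrong dtypes."""


class OrderingError(DurinoseError):
    """Timestamps in a stream are not strictly increasing."""


class PhaseSequenceError(DurinoseError):
    """Phase labels in a stream violate the schedule grammar."""


class InsufficientDataError(DurinoseError):
    """Fewer samples than the operation needs (short window, short phase)."""


class DegenerateDesignError(DurinoseError):
    """A regression design with no usable variation (all times equal,
    constant temperature/humidity, collinear T and RH)."""


class DegenerateVarianceError(DurinoseError):
    """A rank-test variance estimate of zero with no direction information
    (all observations tied across both samples)."""


class NormalizationError(DurinoseError):
    """Anchor reading is zero; relative normalization undefined."""
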