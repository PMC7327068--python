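"""Exception hierarchy.

Everything user-facing derives from :class:`ValidationError` so the CLI can
distinguish bad input (exit code 2) from genuine runtime failure (exit code 1).
"""


class ValidationError(ValueError):
    """Invalid input data or configuration."""


class DuplicateFeatureError(ValidationError):
    """A feature id occurs more than once in an expression table."""


class DuplicateSampleError(ValidationError):
    """A sample id occurs more than once."""


class UnassignedSampleError(ValidationError):
    """An expression column has no group assignment in the sample sheet."""


class NonNumericValueError(ValidationError):
    """A cell of an expression table is missing or not a number."""


class NegativeValueError(ValidationError):
    """An abundance value is negative."""


class MalformedGmtError(ValidationError):
    """A GMT line has fewer than three tab-separated fields."""


class MissingGroupError(ValidationError):
    """A requested group label is absent from the design."""


class ConstantInputError(ValidationError):
    """An operation received a constant vector where variation is required."""


class SampleMismatchError(ValidationError):
    """Expression layers do not share an identical sample set."""


class UniverseError(ValidationError):
    """A differential gene is not contained in the enrichment universe."""


class ConfigError(ValidationError):
    """A simulation or run configuration violates its invariants."""
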