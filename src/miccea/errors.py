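"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command line interface:
validation errors -> 2, data errors -> 3, numeric failures -> 4.
"""


class MicceaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(MicceaError, ValueError):
    """A configuration or argument violates a documented precondition."""

    exit_code = 2


class DataError(MicceaError):
    """Input data are structurally unusable (not merely missing values)."""

    exit_code = 3


class UnpricedCategoryError(DataError):
    """A resource-use category has no entry in the unit-price table."""

    def __init__(self, category: str):
        self.category = category
        super().__init__(f"no unit price for resource-use category {category!r}")


class NumericError(MicceaError):
    """A numeric routine failed to produce a usable result."""

    exit_code = 4


class PipelineError(MicceaError):
    """Failure of a named pipeline stage, wrapping the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        self.exit_code = getattr(cause, "exit_code", 1)
        super().__init__(f"stage {stage!r} failed: {cause}")
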