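"""Exception types shared across the package."""


class LamsalError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LamsalError, ValueError):
    """An argument violates a documented precondition."""


class InvalidDesignError(LamsalError, ValueError):
    """A regression design matrix is rank deficient or otherwise unusable."""


class NumericDomainError(LamsalError, ValueError):
    """Data outside the numeric domain of an operation (e.g. non-positive divisor)."""


class FitFailureError(LamsalError, RuntimeError):
    """A model fit could not be identified from the supplied data."""


class SchemaError(LamsalError, ValueError):
    """A tabular input file does not match the expected sheet/column schema."""
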