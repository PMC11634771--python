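"""Exception hierarchy shared across the pipeline."""


class ForamshiftError(Exception):
    """Base class for all package errors."""


class SchemaError(ForamshiftError):
    """A mandatory column is missing or a column mapping is malformed."""


class DomainError(ForamshiftError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateFractionError(DomainError):
    """Size fraction has zero width in multiplication-factor space."""


class UnitConversionError(ForamshiftError):
    """Raw counts cannot be converted to concentrations (missing volume)."""


class OutOfDomainError(ForamshiftError):
    """A query point lies beyond the clamp tolerance of a gridded field."""


class InsufficientDataError(ForamshiftError):
    """Too few records/levels to evaluate an estimator or test."""


class ParameterError(ForamshiftError):
    """An analysis parameter is inconsistent with the data (e.g. k > n)."""
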