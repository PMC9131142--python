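"""Exception and warning hierarchy for bioage."""


class BioAgeError(Exception):
    """Base class for all bioage errors."""


class CohortFormatError(BioAgeError):
    """The tabular input does not have the required shape (missing columns, bad header)."""


class CellParseError(CohortFormatError):
    """A specific cell could not be parsed; carries row/column context."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class CohortValidationError(BioAgeError):
    """Parsed data violates a cohort invariant (duplicate id, age range, unknown sex...)."""


class DomainError(BioAgeError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ModelSchemaError(BioAgeError):
    """A serialized model document is malformed or has an unsupported schema version."""


class DataQualityWarning(UserWarning):
    """Reference data carries an internal inconsistency that is preserved as printed."""


class ConfigurationWarning(UserWarning):
    """A simulation or screening configuration required an automatic adjustment."""
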