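"""Exception hierarchy for ctclqol."""


class CtclQolError(Exception):
    """Base class for all package errors."""


class SchemaError(CtclQolError):
    """Input file columns do not match the instrument definition."""


class ResponseValidationError(CtclQolError):
    """A response code violates the instrument's coding rules."""

    def __init__(self, message: str, person_id=None, item_id=None):
        super().__init__(message)
        self.person_id = person_id
        self.item_id = item_id


class IncompleteRecordError(CtclQolError):
    """A respondent left one or more required items blank."""


class ParameterError(CtclQolError):
    """Simulation or model parameters are inconsistent."""


class ComparisonError(CtclQolError):
    """Two calibrations being compared were not fit to the same data."""


class InsufficientDataError(CtclQolError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(CtclQolError):
    """A correlation is undefined because an input variable is constant."""


class UnmappedScoreError(CtclQolError):
    """A scaled score that no raw total produces."""


class ImpossibleInputError(CtclQolError):
    """A raw total outside the attainable range of the instrument."""
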