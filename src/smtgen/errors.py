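"""Exception hierarchy for smtgen.

Every error raised deliberately by the package derives from :class:`SmtgenError`,
so callers (and the CLI) can distinguish package failures from programming bugs.
"""


class SmtgenError(Exception):
    """Base class for all smtgen errors."""


class ConfigurationError(SmtgenError):
    """A configuration object is internally inconsistent or incompatible."""


class ParameterError(SmtgenError):
    """An operation received an out-of-range or nonsensical parameter."""


class ValidationError(SmtgenError):
    """Input data failed validation; carries a list of offending records."""

    def __init__(self, message: str, offending_rows: list | None = None):
        super().__init__(message)
        self.offending_rows = offending_rows or []


class ParseError(SmtgenError):
    """Serialized input could not be parsed."""


class CalibrationError(SmtgenError):
    """Calibration could not produce a valid (nonempty) ensemble."""
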