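"""Exception hierarchy for the outbreaklaw package."""


class OutbreakLawError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OutbreakLawError):
    """A run or input configuration is invalid (missing column, bad era, ...)."""


class ValidationError(OutbreakLawError):
    """Input rows failed validation (non-integer or sub-unit outbreak sizes).

    Carries the offending row indices/values in :attr:`rows`.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class EmptyPeriodError(OutbreakLawError):
    """No outbreak records fall inside the requested period."""


class DegenerateDataError(OutbreakLawError):
    """Too few distinct sizes to fit a tail model (likelihood unbounded)."""


class DivergentTailError(OutbreakLawError):
    """A closed-form tail expectation diverges (alpha <= 2) and no cap was configured."""
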