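"""Exception types shared across the package."""


class BotanicadError(ValueError):
    """Base class for all validation and input errors raised here."""


class ParameterError(BotanicadError):
    """A configuration value or function parameter is out of range."""


class InputError(BotanicadError):
    """Input data (trace, table, window) is malformed or empty."""


class CalibrationError(BotanicadError):
    """Calibration standards are unusable (e.g. all-zero areas)."""


class FormulaError(BotanicadError):
    """A molecular-formula string could not be parsed."""
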