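"""Exception hierarchy shared across the package."""


class LtraError(Exception):
    """Base class for all package-specific errors."""


class AgeRangeError(LtraError, ValueError):
    """An age (or age reached over a horizon) falls outside a profile's valid range."""


class ContractError(LtraError, ValueError):
    """A call violates an operation's precondition (bad lengths, bounds, types)."""


class GrowthCalibrationError(LtraError, RuntimeError):
    """No growth rate in the admissible bracket reproduces the requested annuity total."""


class UnknownFixtureError(LtraError, KeyError):
    """Requested scenario fixture name is not registered."""


class ConfigError(LtraError, ValueError):
    """A run configuration failed schema validation."""
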