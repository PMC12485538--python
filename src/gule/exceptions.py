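"""Exception hierarchy for the gule package."""


class GuleError(Exception):
    """Base class for all gule errors."""


class DataError(GuleError):
    """Raised when input data are malformed, unparseable, or violate a precondition."""


class ConfigError(GuleError):
    """Raised for invalid configuration or parameter values."""
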