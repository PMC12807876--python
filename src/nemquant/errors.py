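"""Exception types shared across the pipeline."""


class NemquantError(Exception):
    """Base class for all package errors."""


class ValidationError(NemquantError, ValueError):
    """Raised when inputs violate a documented precondition."""


class ConfigError(NemquantError, ValueError):
    """Raised for malformed or unknown configuration keys."""
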