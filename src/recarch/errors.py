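"""Exception types shared across the package."""


class RecArchError(Exception):
    """Base class for package errors."""


class ConfigError(RecArchError):
    """Inconsistent or malformed configuration."""


class StateError(RecArchError):
    """Operation called in an invalid simulation state."""
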