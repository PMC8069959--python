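"""Exception hierarchy shared across the pipeline stages."""


class ImprintGuardError(Exception):
    """Base class for all package errors."""


class InputError(ImprintGuardError, ValueError):
    """Malformed or out-of-contract input data."""


class ConfigError(ImprintGuardError, ValueError):
    """Invalid configuration or parameter combination."""
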