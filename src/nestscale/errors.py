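"""Exception types shared across the package."""


class NestscaleError(Exception):
    """Base class for package errors."""


class DegenerateInputError(NestscaleError, ValueError):
    """An operation received an input it cannot meaningfully process
    (empty sequence, fewer calibration points than parameters, ...)."""


class ConfigurationError(NestscaleError, ValueError):
    """Inconsistent configuration or parameter shapes."""
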