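"""Package-wide exception types."""


class NlrkitError(Exception):
    """Base class for all errors raised by nlrkit."""


class ConfigurationError(NlrkitError):
    """Invalid generator or pipeline configuration."""
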