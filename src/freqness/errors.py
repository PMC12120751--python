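"""Exception hierarchy shared across the package."""


class FreqnessError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FreqnessError):
    """Invalid or missing configuration (e.g. unknown key, missing sampling rate)."""


class DataError(FreqnessError):
    """Malformed or degenerate input data (non-finite values, shape mismatch...)."""


class UnsupportedOperationError(FreqnessError):
    """Operation requested on an object that lacks the required metadata."""


class DependencyError(FreqnessError):
    """A pipeline stage was requested before the stage it depends on."""
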