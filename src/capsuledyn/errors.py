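"""Exception hierarchy shared across the pipeline."""


class CapsuledynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CapsuledynError, ValueError):
    """Invalid simulation, model, or pipeline configuration."""


class InputFormatError(CapsuledynError, ValueError):
    """A file or in-memory table violates the expected dialect."""


class NumericDomainError(CapsuledynError, ValueError):
    """A value fell outside the mathematically valid domain (e.g. log of 0)."""
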