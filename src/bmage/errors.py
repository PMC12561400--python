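"""Exception hierarchy shared across the package."""


class BmageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BmageError, ValueError):
    """Invalid configuration or study-design field."""


class DomainError(BmageError, ValueError):
    """Input outside the mathematical domain of an operation."""


class PipelineError(BmageError, RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""
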