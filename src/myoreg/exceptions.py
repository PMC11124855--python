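"""Exception hierarchy shared across the package."""


class MyoregError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MyoregError, ValueError):
    """Raised when data handed to an operation violates its preconditions."""


class ConfigurationError(MyoregError, ValueError):
    """Raised when a configuration object is internally inconsistent."""
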