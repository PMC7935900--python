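"""Exception hierarchy shared across the package."""


class MethexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MethexError):
    """An invalid configuration value; the message names the offending field."""


class InputError(MethexError):
    """Malformed or inconsistent input data (files or in-memory tables)."""


class MissingGeneError(InputError):
    """A required gene symbol is absent from an expression matrix."""


class StageError(MethexError):
    """A pipeline stage cannot run because its inputs are missing."""
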