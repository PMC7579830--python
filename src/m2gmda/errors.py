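"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class M2GMDAError(Exception):
    """Base class for all package errors."""


class ConfigError(M2GMDAError):
    """Invalid configuration value or malformed config file."""


class DataError(M2GMDAError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(DataError):
    """Input that makes a computation undefined (e.g. all-zero profiles)."""


class InvalidDAGError(DataError):
    """Disease graph is cyclic or disconnected from its target term."""
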