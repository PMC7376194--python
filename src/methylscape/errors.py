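"""Exception taxonomy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class MethylscapeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MethylscapeError):
    """A parameter or configuration value is invalid or missing."""


class DataError(MethylscapeError):
    """Input data violates a format or invariant contract."""
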