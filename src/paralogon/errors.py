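"""Exception hierarchy shared across the package.

``ConfigError`` and ``DataError`` map onto the CLI exit codes 2 and 3.
"""


class ParalogonError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ParalogonError):
    """Invalid configuration (bad thresholds, malformed config file, ...)."""


class DataError(ParalogonError):
    """Invalid input data (missing columns, duplicate ids, broken invariants)."""
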