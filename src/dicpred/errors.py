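"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
anything else -> 4.
"""


class DicpredError(Exception):
    """Base class for package errors."""


class ConfigError(DicpredError):
    """Invalid configuration or missing input file."""


class ParameterError(DicpredError, ValueError):
    """An argument is outside its documented domain."""


class DataError(DicpredError, ValueError):
    """Input data violates a schema or type invariant."""
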