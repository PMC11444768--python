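"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class GelsenseError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(GelsenseError):
    """Invalid configuration, parameters or geometry."""

    exit_code = 2


class DataError(GelsenseError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class NumericalError(GelsenseError):
    """A numerical procedure failed to converge or produced garbage."""

    exit_code = 4
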