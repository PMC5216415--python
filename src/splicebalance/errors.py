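"""Exception hierarchy shared across the package.

Configuration problems (bad parameters, unknown methods, malformed configs)
and data problems (inconsistent tables, unmapped probes, degenerate inputs)
are distinguished so the command-line layer can map them to exit codes
2 and 3 respectively.
"""


class SpliceBalanceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpliceBalanceError):
    """Invalid parameters, unknown methods or malformed configuration."""


class DataError(SpliceBalanceError):
    """Inconsistent, degenerate or otherwise unusable input data."""
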