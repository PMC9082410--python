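"""Exception hierarchy shared across the package.

Exit codes follow the pipeline contract: 2 configuration, 3 data,
4 numerical failure.
"""


class HealthineqError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(HealthineqError):
    """Invalid configuration (bad distribution spec, unknown option...)."""

    exit_code = 2


class DataError(HealthineqError):
    """Invalid or degenerate input data."""

    exit_code = 3


class NumericalError(HealthineqError):
    """Numerical failure (non-convergence, rank deficiency...)."""

    exit_code = 4
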