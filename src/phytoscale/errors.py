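"""Exception hierarchy; the CLI maps these onto exit codes."""


class PhytoscaleError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PhytoscaleError):
    """Invalid or inconsistent configuration (exit code 2)."""

    exit_code = 2


class DataError(PhytoscaleError):
    """Invalid input data: bad values, missing columns, empty tables (exit code 3)."""

    exit_code = 3


class ConvergenceError(PhytoscaleError):
    """An optimisation failed to produce a usable fit (exit code 4)."""

    exit_code = 4


class IdentifiabilityError(ConvergenceError):
    """The likelihood is flat in a parameter; the message names it."""
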