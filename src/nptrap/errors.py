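"""Exception hierarchy shared across the package.

Each error class maps to a distinct CLI exit code (see :mod:`nptrap.cli`).
"""


class NPTrapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NPTrapError):
    """Invalid configuration: bad parameter values or unknown keys."""

    exit_code = 2


class ValidationError(NPTrapError):
    """Input data violates a documented invariant (e.g. TcReadCount > ReadCount)."""

    exit_code = 3


class EstimationError(NPTrapError):
    """A statistical estimate cannot be formed from the given data."""

    exit_code = 4


class ParseError(NPTrapError):
    """A file does not conform to its declared format."""

    exit_code = 5


class EmptyTableError(NPTrapError):
    """An operation received a table with no usable rows."""

    exit_code = 6
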