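"""Exception hierarchy. Each class maps to a distinct CLI exit code."""


class EcisError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidArgumentError(EcisError, ValueError):
    """A value violates a precondition (non-positive frequency, zero impedance...)."""

    exit_code = 2


class InsufficientDataError(EcisError):
    """Too few data points survive filtering to support the requested analysis."""

    exit_code = 3


class OutOfRangeError(EcisError):
    """Interpolation or lookup outside the supported range would require extrapolation."""

    exit_code = 4


class ParseError(EcisError):
    """A file could not be parsed; the message names the offending column/row."""

    exit_code = 5


class DegenerateDataError(EcisError):
    """Input is degenerate for the requested statistic (constant image, zero variance...)."""

    exit_code = 6


class PipelineError(EcisError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    exit_code = 7
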