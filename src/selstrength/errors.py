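"""Exception hierarchy.

Two broad classes matter for the command line: problems with the
user's inputs (exit code 1) and numerical failures during estimation
or simulation (exit code 2).
"""


class SelstrengthError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(SelstrengthError):
    """Malformed or inconsistent user input (tables, configs, specs)."""

    exit_code = 1


class DomainError(InputError):
    """A covariate value outside the domain of a transform (e.g. log of a
    non-positive value)."""


class RasterFormatError(InputError):
    """Malformed ESRI ASCII grid."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class NumericalError(SelstrengthError):
    """Estimation or simulation failed for numerical reasons."""

    exit_code = 2


class EstimationError(NumericalError):
    """A model cannot be estimated from the given data (flat or
    rank-deficient likelihood)."""
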