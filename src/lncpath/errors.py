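"""Exception hierarchy.

Each error class carries the process exit code the CLI maps it to:
I/O and parse failures exit 2, validation failures 3, degenerate
statistical inputs 4. Anything else is an unexpected crash (1).
"""


class LncPathError(Exception):
    """Base class for all errors raised by lncpath."""

    exit_code = 1


class InputIOError(LncPathError):
    """A file is missing, unreadable, or not in the expected dialect."""

    exit_code = 2


class MatrixParseError(InputIOError):
    """A cell of an expression matrix could not be parsed as a finite number."""


class GmtFormatError(InputIOError):
    """A GMT line violates the name/description/members layout."""


class ValidationError(LncPathError):
    """Inputs parsed but violate an invariant (duplicates, shape, overlap...)."""

    exit_code = 3


class HarmonizationError(ValidationError):
    """No samples shared between the lncRNA and coding matrices after barcode truncation."""


class TargetNotFoundError(ValidationError):
    """The requested gene identifier is absent from the matrix."""


class ConfigError(ValidationError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(LncPathError):
    """A statistic is undefined on this input (zero variance, all-hit list, ...)."""

    exit_code = 4
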