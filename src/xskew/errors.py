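"""Exception hierarchy and stable CLI exit codes."""

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_DEGENERATE = 3


class XskewError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = EXIT_VALIDATION


class InvalidParameterError(XskewError, ValueError):
    """A configuration value or function argument is outside its valid range."""


class AssayFailureError(XskewError):
    """A lane cannot be interpreted (e.g. a pre-digestion band is absent)."""


class OverDigestionError(AssayFailureError):
    """Both post-digestion bands are absent: over-digestion or failed PCR."""


class InputValidationError(XskewError, ValueError):
    """A data file failed validation; the message names the offending line."""


class DegenerateTableError(XskewError, ValueError):
    """A contingency table has a zero margin and cannot be tested."""

    exit_code = EXIT_DEGENERATE


class InsufficientDataError(XskewError, ValueError):
    """Too few observations for the requested statistic."""

    exit_code = EXIT_DEGENERATE
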