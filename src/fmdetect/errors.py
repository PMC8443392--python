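"""Exception hierarchy shared by all fmdetect modules."""


class FmdetectError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FmdetectError):
    """A file has the wrong structure (column count, missing header, ...)."""


class ParseError(FmdetectError):
    """A file row could not be parsed; the message names the offending line."""


class ParameterError(FmdetectError):
    """An algorithm parameter violates its contract (e.g. R <= 0, T0 > n)."""


class DegenerateInputError(FmdetectError):
    """An input signal is degenerate for the requested operation (e.g. zero norm)."""


class DataError(FmdetectError):
    """Input data contain non-finite or otherwise unusable values."""


class InstabilityError(FmdetectError):
    """An iterative algorithm diverged (typically: LMS step size too large)."""


class MetricsUndefinedError(FmdetectError):
    """A requested metric is undefined for the given counts (e.g. TMF == 0)."""


class ContractError(FmdetectError):
    """An internal interface contract was violated (wrong cardinality, mismatch)."""
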