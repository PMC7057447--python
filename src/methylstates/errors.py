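"""Exception hierarchy for methylstates."""


class MethylstatesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethylstatesError):
    """An input file could not be parsed in the declared format."""


class ValidationError(MethylstatesError):
    """Parsed input violates a domain invariant (bounds, ordering, ...)."""


class InitializationError(MethylstatesError):
    """HMM initialization produced a degenerate starting point.

    Typically raised when the hard threshold used to seed the two
    hidden states leaves one state with no assigned observations; the
    remedy is to move the cutoff or to inspect the input distribution.
    """
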