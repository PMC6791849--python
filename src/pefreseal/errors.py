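"""Exception hierarchy shared by all pefreseal modules."""


class PefresealError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PefresealError, ValueError):
    """Invalid input: bad parameter value, malformed table, inconsistent config."""


class DomainError(PefresealError, ValueError):
    """Input outside the mathematical domain of a model (e.g. N_m >= N_s)."""


class ConvergenceError(PefresealError, RuntimeError):
    """A fit failed to converge and the caller asked for a hard error."""
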