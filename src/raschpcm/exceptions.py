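"""Exception hierarchy."""


class RaschError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RaschError, ValueError):
    """An argument violates a documented precondition."""


class DataError(RaschError, ValueError):
    """Input data fails validation (out-of-range codes, empty items...)."""


class ConvergenceError(RaschError, RuntimeError):
    """An iterative fit failed to converge; message carries the gradient norm."""


class UndefinedPersonError(RaschError, ValueError):
    """A person has no observed responses, so no ability can be estimated."""
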