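"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition.

    The CLI maps this to exit code 1 (user/input error), while any other
    exception maps to exit code 2 (runtime error).
    """


class ConvergenceWarning(UserWarning):
    """Emitted when an iterative fit stops at its iteration cap."""
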