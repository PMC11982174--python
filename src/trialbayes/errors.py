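"""Exception types distinguishing bad inputs from numerical failures."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition."""


class NumericalError(RuntimeError):
    """A numerical routine failed to converge; carries diagnostics in args."""
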