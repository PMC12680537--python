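"""Exception types shared across modules."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition (negative mass, NaN, ...)."""


class UndefinedValueError(ValueError):
    """A quantity is mathematically undefined for the given input (e.g. zero denominator)."""


class FixtureError(ValueError):
    """A bundled or user-supplied fixture file failed validation."""
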