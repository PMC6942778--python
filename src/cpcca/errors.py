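"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class SingularityError(ValidationError):
    """A covariance matrix is singular; retry with ridge > 0."""
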