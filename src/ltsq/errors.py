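"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateMarginalsError(ValidationError):
    """Raised when an agreement statistic is undefined because the expected
    chance agreement equals 1 while observed agreement does not."""


class StageDependencyError(RuntimeError):
    """Raised by the pipeline when an upstream artifact is missing."""
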