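"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class NoContactError(RuntimeError):
    """Raised when a force series never exceeds the contact threshold.

    Callers that prefer a sentinel can use ``detect_contact(..., missing="none")``.
    """
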