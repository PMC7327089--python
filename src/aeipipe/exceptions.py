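"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Input violates a schema or parameter constraint."""


class DegenerateInputError(ValueError):
    """Input is syntactically valid but statistically degenerate
    (e.g. zero-variance paired differences, zero testable genes)."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested without its required upstream output."""
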