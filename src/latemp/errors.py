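"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid study design, effect specification, or pipeline parameter."""


class ValidationError(ValueError):
    """Input data violates a structural invariant (lengths, rates, monotonicity)."""


class DatasetFormatError(ValueError):
    """A dataset file on disk is malformed; the message names file and row/column."""
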