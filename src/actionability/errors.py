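"""Exception hierarchy for the actionability package."""


class ActionabilityError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ActionabilityError, ValueError):
    """A probability vector, table, or config violates its invariants."""


class AlignmentError(ActionabilityError, ValueError):
    """Two belief tables cannot be paired (label sets or sample ids differ)."""
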