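"""Exception hierarchy.

``ValueError`` subclasses flag bad arguments or malformed inputs;
``ComputationError`` flags numerically impossible requests (singular
covariance, empty denominators) discovered mid-computation.
"""


class FormatError(ValueError):
    """Input file violates the declared dialect (duplicated ids, ragged rows)."""


class ComputationError(RuntimeError):
    """A requested quantity cannot be computed from the given data."""
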