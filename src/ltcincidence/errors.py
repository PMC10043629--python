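"""Typed exceptions raised across the pipeline.

Every stage fails with one of these so the CLI can abort with a
stage-named message instead of a bare traceback.
"""


class LtcError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(LtcError):
    """A table file does not match the documented column schema."""


class ValidationError(LtcError):
    """A table parses but violates an invariant (counts, ranges, keys)."""


class CoverageError(LtcError):
    """A query lies outside the tabulated hull (no silent extrapolation)."""


class FittingError(LtcError):
    """The regression design is degenerate (too few points, rank deficiency)."""


class DomainError(LtcError):
    """An estimator input is outside the admissible domain (e.g. p >= 1)."""


class IntegrationError(LtcError):
    """The compartment solver produced a non-finite state."""
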