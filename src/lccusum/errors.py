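"""Exception hierarchy shared across the package.

All validation-type failures derive from :class:`ValidationError` so callers
(and the CLI) can map them to a single exit code; model-fitting failures are
kept separate because they signal a numerical rather than an input problem.
"""


class LccusumError(Exception):
    """Base class for all package errors."""


class ValidationError(LccusumError, ValueError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A CSV/JSON input is missing a required column or field."""


class DegenerateSchemeError(ValidationError):
    """Chart constants cannot be derived (p0 == p1 or a rate at 0/1)."""


class PhaseError(ValidationError):
    """A scheme was used with the wrong chart phase."""


class ConvergenceError(LccusumError, RuntimeError):
    """A model fit failed to converge (e.g. complete separation)."""
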