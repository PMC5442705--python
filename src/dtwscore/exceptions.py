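"""Exception hierarchy for dtwscore.

Every error raised on a documented failure path derives from
:class:`DtwscoreError`, so callers (and the CLI) can distinguish domain
errors from programming errors.
"""


class DtwscoreError(Exception):
    """Base class for all dtwscore domain errors."""


class ValidationError(DtwscoreError, ValueError):
    """Input data violates a documented contract (negative value, missing
    metadata, empty file, length mismatch, ...)."""


class EmptyResultError(DtwscoreError):
    """An operation produced an empty result where at least one element is
    required (e.g. no gene survives quality filtering)."""


class DegenerateFitError(DtwscoreError):
    """A model fit is degenerate (all-identical data with K > 1, every
    candidate fit failed, ...)."""
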