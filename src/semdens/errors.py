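"""Exception hierarchy shared across the package.

``SkipSentence`` is a control-flow signal, not a hard error: pipeline stages
catch it, log the sentence, and move on.  Everything else aborts the caller.
"""


class SemdensError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SemdensError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(SemdensError, ValueError):
    """Numerically degenerate input (zero vector, zero variance, zero SE)."""


class ConfigurationError(SemdensError):
    """A required backend or path is missing or misconfigured."""


class NumericInstabilityError(SemdensError):
    """Gradient descent diverged (non-finite cost); names the learning rate."""


class NoBoundaryError(SemdensError):
    """Decision boundary undefined (zero slope)."""


class SkipSentence(SemdensError):
    """Sentence cannot enter the analysis (no content words in vocabulary,
    zero resultant, no nonzero unpacking weights).  Callers skip and log."""
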