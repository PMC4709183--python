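"""Exception hierarchy shared across the pipeline."""


class PLVSpellerError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PLVSpellerError, ValueError):
    """An argument violates a precondition of the operation."""


class DegenerateInputError(PLVSpellerError, ValueError):
    """Input is formally valid but degenerate (e.g. zero variance, all-zero signal)."""


class EstimationError(PLVSpellerError, RuntimeError):
    """A statistical estimation step failed (e.g. rank-deficient decomposition)."""
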