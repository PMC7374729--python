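"""Exception hierarchy for stabscan."""


class StabscanError(Exception):
    """Base class for all stabscan errors."""


class DegenerateBaselineError(StabscanError):
    """Folded and unfolded baselines are identical; alpha is undefined."""


class NoTransitionDataError(StabscanError):
    """No curve points survive the transition-region retention window."""


class DomainError(StabscanError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientDataError(StabscanError):
    """Too few points/values for a fit or statistical test."""


class ParseError(StabscanError):
    """An input file could not be parsed."""


class StageError(StabscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
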