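"""Exception and warning types used across the package."""


class CowBWError(Exception):
    """Base class for package errors."""


class DomainError(CowBWError, ValueError):
    """An input lies outside the mathematical domain of an equation."""


class InconsistencyError(CowBWError, ValueError):
    """Inputs are jointly impossible (e.g. pregnancy compound >= body weight)."""


class SingularFitError(CowBWError, ValueError):
    """A regression design is degenerate (zero variance, all-zero predictor)."""


class BreakpointError(CowBWError, ValueError):
    """The segmented-model breakpoint is unidentifiable from the data."""


class HerdValidationError(CowBWError, ValueError):
    """One or more herd CSV rows failed validation."""

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems)
        super().__init__(f"invalid herd records: {lines}")


class ExtrapolationWarning(UserWarning):
    """Input outside the range the prediction equations were developed on."""


class ClampingWarning(UserWarning):
    """A negative intermediate component was clamped to zero."""


class FallbackWarning(UserWarning):
    """A requested model could not be used and a documented fallback was."""
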