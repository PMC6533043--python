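"""Exception hierarchy shared across the package."""


class AttricalError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(AttricalError):
    """A simulation or pipeline configuration violates its invariants."""


class DegenerateInputError(AttricalError):
    """Input admits no defined answer (e.g. a single label, no rank variation)."""


class SingularDesignError(AttricalError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class UnderIdentifiedError(AttricalError):
    """Fewer usable instruments than endogenous regressors."""


class EstimationImpossibleError(AttricalError):
    """A model cannot be estimated at all on the given sample."""


class MissingInputError(AttricalError):
    """A pipeline stage was invoked before the stage that produces its input."""
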