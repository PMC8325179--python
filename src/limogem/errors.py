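"""Exception hierarchy for limogem."""


class LimogemError(Exception):
    """Base class for all package errors."""


class FormatError(LimogemError):
    """A file could not be parsed under the declared dialect."""


class IntegrityError(LimogemError):
    """A model references an undeclared metabolite, gene or reaction."""


class ValidationError(LimogemError):
    """A model or reaction violates a structural invariant."""


class ConfigurationError(LimogemError):
    """An option, dialect or override does not match the data it governs."""


class ReconciliationError(LimogemError):
    """Two templates define the same metabolite id incompatibly."""


class MediumError(LimogemError):
    """A medium references a metabolite the model cannot exchange."""


class UnfillableError(LimogemError):
    """Gap-filling cannot reach the growth floor even with the full pool."""

    def __init__(self, message: str, blocked_precursors=()):
        super().__init__(message)
        self.blocked_precursors = tuple(blocked_precursors)


class SolverError(LimogemError):
    """The LP backend failed for a reason other than infeasible/unbounded."""


class GenerationError(LimogemError):
    """A synthetic-data spec cannot produce a viable network."""
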