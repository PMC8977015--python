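"""Exception hierarchy shared across the package."""


class EpistabError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EpistabError, ValueError):
    """A parameter is outside its documented domain."""


class MalformedModelError(EpistabError, ValueError):
    """A model file or entry set is structurally invalid."""


class ExpressionError(MalformedModelError):
    """A penetrance expression is unparsable or uses forbidden symbols."""


class UnsupportedModelError(EpistabError):
    """The model has no single dominating penetrance expression, so the
    max-penetrance constraint is ill-posed."""


class UnsolvableConfigurationError(EpistabError):
    """No admissible real solution exists for the requested configuration.

    This is an expected outcome for some model/MAF/parameter combinations;
    not every prevalence or heritability is attainable by every model.
    """


class SolverTimeoutError(EpistabError):
    """The solver exceeded its time budget."""

    def __init__(self, message: str, elapsed: float | None = None):
        super().__init__(message)
        self.elapsed = elapsed


class InconsistentSolutionError(EpistabError):
    """A solution produced penetrances materially outside [0, 1]."""


class UndefinedHeritabilityError(EpistabError):
    """Heritability is undefined because prevalence is 0 or 1."""
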