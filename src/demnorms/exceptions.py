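"""Exception hierarchy for demnorms.

Every error raised deliberately by the package derives from
:class:`DemNormsError`, so callers (and the CLI) can catch one type.
"""


class DemNormsError(Exception):
    """Base class for all demnorms errors."""


class InvalidParameterError(DemNormsError, ValueError):
    """A parameter value is outside its legal domain (non-finite, negative, ...)."""


class DegenerateInputError(DemNormsError, ValueError):
    """Input data are structurally unusable (zero variance, impossible counts)."""


class DomainError(DemNormsError, ValueError):
    """A demographic value lies outside the domain of a correction equation."""


class InsufficientSampleError(DemNormsError, ValueError):
    """The sample is too small for the requested tolerance limit.

    ``min_n`` carries the smallest sample size for which the limit exists.
    """

    def __init__(self, msg: str, min_n: int | None = None):
        super().__init__(msg)
        self.min_n = min_n


class NumericalFailureError(DemNormsError, RuntimeError):
    """A numerical procedure failed (singular design, non-convergence)."""


class ConfigurationError(DemNormsError, ValueError):
    """A configuration object or norms asset is invalid or incomplete."""


class CohortParseError(DemNormsError, ValueError):
    """A cohort or card CSV failed validation; ``row`` is the offending row index."""

    def __init__(self, msg: str, row: int | None = None):
        super().__init__(msg)
        self.row = row
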