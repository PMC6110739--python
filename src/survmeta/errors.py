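"""Exception hierarchy for the survmeta pipeline."""


class SurvmetaError(Exception):
    """Base class for all survmeta errors."""


class MetadataError(SurvmetaError):
    """Invalid metadata bundle, layer file, or override."""


class SchemaError(MetadataError):
    """A layer file violates the codebook schema (duplicate codes,
    overlapping tokens, unknown columns); the message names the row."""


class LoadError(SurvmetaError):
    """Raw dataset cannot be loaded under the given metadata
    (e.g. negative survival times)."""


class CriterionError(SurvmetaError):
    """A filter criterion is illegal for the variable it targets."""


class InsufficientDataError(SurvmetaError):
    """Too few observations for the requested statistical operation."""


class DegenerateGroupError(SurvmetaError):
    """A comparison group has too few complete cases."""


class ComparisonImpossibleError(SurvmetaError):
    """A factor collapses to a single level; no contrast exists."""


class StratifierTypeError(SurvmetaError):
    """The stratifying variable is not categorical."""


class IdentifiabilityError(SurvmetaError):
    """A covariate is constant; its coefficient is not identified."""


class SeparationError(SurvmetaError):
    """Monotone partial likelihood: a coefficient diverges."""


class ConvergenceError(SurvmetaError):
    """Newton-Raphson failed to converge within max_iter."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class GroupExplosionError(SurvmetaError):
    """A survival formula expands to too many covariate-level groups."""


class SimSpecError(SurvmetaError):
    """Invalid simulation specification (infeasible censoring target,
    bad rates or probabilities)."""
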