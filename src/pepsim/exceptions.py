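"""Exception and warning types shared across pepsim."""


class PepsimError(Exception):
    """Base class for all pepsim errors."""


class InvalidInputError(PepsimError, ValueError):
    """A numeric input is non-finite, non-positive where positivity is
    required, or otherwise outside the meaning of the quantity."""


class DomainBoundsError(PepsimError, ValueError):
    """A query point lies outside a model's validated pH/temperature domain
    and the extrapolation policy forbids evaluating there."""


class ModelLookupError(PepsimError, KeyError):
    """Unknown (species, variant) combination requested from the built-in
    model registry."""


class DesignError(PepsimError, ValueError):
    """An experimental design is infeasible: fewer usable observations than
    model terms, or impossible D-optimal selection sizes."""


class RankDeficiencyError(PepsimError, ValueError):
    """The design matrix is singular; the message names the collinear
    columns."""


class TransformError(PepsimError, ValueError):
    """The response transform cannot be applied (log10 of a non-positive
    activity)."""


class ProfileRangeError(PepsimError, ValueError):
    """A time query falls outside the span of a digestion profile or pH
    curve; conditions are never extrapolated."""


class GridMismatchError(PepsimError, ValueError):
    """Two simulation results were compared point-by-point but do not share
    a time grid."""


class NoFitError(PepsimError, ValueError):
    """An inactivation-rate fit was requested but no (or too few) records
    with positive residual activity are available."""


class CoefficientSanityWarning(UserWarning):
    """A surface model predicts a physically implausible activity at its own
    reference condition, suggesting transcribed-coefficient damage."""


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the model's validated domain under
    the default ``warn`` policy."""
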