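"""Polynomial pH x temperature activity surfaces for pepsin.

The central object is :class:`ActivitySurfaceModel`: a polynomial in pH and
temperature (deg C) evaluated on the log10 scale, whose antilog is pepsin
activity expressed as a percentage of the activity at the reference optimum
(pH 2, 37 deg C).  Two published surfaces are built in, one for human
gastric-fluid pepsin and one for commercial porcine pepsin, each fitted over
pH 1-7 and 4-60 deg C.  Because the published human equation carries an
obvious transcription error in its temperature-linear coefficient, every
built-in surface exists in two variants:

``as_printed``
    the coefficients exactly as published, warts and all;
``corrected``
    the same coefficients with documented editorial amendments only (for the
    human surface, temperature-linear 0.88912 -> 0.088912, which restores a
    ~100% prediction at the optimum; the porcine surface has no defensible
    single-coefficient amendment and is left identical).

Activities above 100% are meaningful (conditions can beat the nominal
optimum) and are never clipped.  For surfaces whose absolute calibration is
suspect, :func:`predict_relative` — activity re-normalised by the surface's
own value at the reference condition — is the recommended output.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import (
    CoefficientSanityWarning,
    DomainBoundsError,
    ExtrapolationWarning,
    InvalidInputError,
    ModelLookupError,
)

__all__ = [
    "PolyTerm",
    "ActivitySurfaceModel",
    "Prediction",
    "ExtrapolationPolicy",
    "evaluate_log10",
    "predict_activity",
    "predict_relative",
    "builtin_model",
    "BUILTIN_SPECIES",
    "BUILTIN_VARIANTS",
]

ExtrapolationPolicy = Literal["warn", "forbid", "allow"]

#: Default validated factor domain: pH 1-7, temperature 4-60 deg C.
DEFAULT_PH_DOMAIN = (1.0, 7.0)
DEFAULT_TEMP_DOMAIN = (4.0, 60.0)
#: Reference optimum condition at which relative activity is defined as 100%.
DEFAULT_REFERENCE = (2.0, 37.0)

_MAX_EXPONENT = 3


@dataclass(frozen=True)
class PolyTerm:
    """One monomial ``coefficient * pH**ph_power * temp**temp_power``."""

    ph_power: int
    temp_power: int
    coefficient: float

    def __post_init__(self) -> None:
        for name, power in (("ph_power", self.ph_power), ("temp_power", self.temp_power)):
            if not isinstance(power, (int, np.integer)) or power < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {power!r}")
            if power > _MAX_EXPONENT:
                raise InvalidInputError(f"{name}={power} exceeds the maximum exponent {_MAX_EXPONENT}")
        if not math.isfinite(self.coefficient):
            raise InvalidInputError("coefficient must be finite")

    @property
    def powers(self) -> tuple[int, int]:
        return (int(self.ph_power), int(self.temp_power))


@dataclass(frozen=True)
class ActivitySurfaceModel:
    """A log10-polynomial activity surface with domain and normalisation.

    Parameters
    ----------
    species
        ``"human"``, ``"porcine"`` or ``"custom"``.
    variant
        ``"as_printed"``, ``"corrected"`` or ``"fitted"``.
    terms
        Monomials of the polynomial; exponents are unique pairs and the
        intercept ``(0, 0)`` must be present.
    ph_domain, temp_domain
        Closed intervals over which the surface is considered validated.
        Queries outside are extrapolations (allowed, but flagged).
    reference
        ``(pH, temp)`` pair defining the 100% normalisation point; must lie
        inside the domain.
    provenance
        Free-text note on where the coefficients come from (printed
        equation, editorial amendment, refit from data, ...).
    """

    species: str
    variant: str
    terms: tuple[PolyTerm, ...]
    ph_domain: tuple[float, float] = DEFAULT_PH_DOMAIN
    temp_domain: tuple[float, float] = DEFAULT_TEMP_DOMAIN
    reference: tuple[float, float] = DEFAULT_REFERENCE
    transform: str = "log10"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.transform != "log10":
            raise InvalidInputError("only the log10 transform is supported")
        if not self.terms:
            raise InvalidInputError("model must have at least one term")
        powers = [t.powers for t in self.terms]
        if len(set(powers)) != len(powers):
            raise InvalidInputError("duplicate (ph_power, temp_power) pairs in terms")
        if (0, 0) not in powers:
            raise InvalidInputError("model must include the intercept term (0, 0)")
        for name, (lo, hi) in (("ph_domain", self.ph_domain), ("temp_domain", self.temp_domain)):
            if not (lo < hi):
                raise InvalidInputError(f"{name} lower bound must be below upper bound")
        ph_ref, temp_ref = self.reference
        if not (self.ph_domain[0] <= ph_ref <= self.ph_domain[1]
                and self.temp_domain[0] <= temp_ref <= self.temp_domain[1]):
            raise InvalidInputError("reference condition must lie inside the domain")
        object.__setattr__(self, "terms", tuple(self.terms))

    # -- geometry ---------------------------------------------------------

    def in_domain(self, ph: float, temp: float) -> bool:
        return bool(
            self.ph_domain[0] <= ph <= self.ph_domain[1]
            and self.temp_domain[0] <= temp <= self.temp_domain[1]
        )

    def coefficient(self, ph_power: int, temp_power: int) -> float:
        """Coefficient of a monomial, 0.0 if the term is absent."""
        for t in self.terms:
            if t.powers == (ph_power, temp_power):
                return t.coefficient
        return 0.0

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "variant": self.variant,
            "transform": self.transform,
            "reference": {"ph": self.reference[0], "temp_c": self.reference[1]},
            "domain": {"ph": list(self.ph_domain), "temp_c": list(self.temp_domain)},
            "terms": [
                {"ph_pow": t.ph_power, "temp_pow": t.temp_power, "coef": t.coefficient}
                for t in self.terms
            ],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActivitySurfaceModel":
        return cls(
            species=d["species"],
            variant=d["variant"],
            terms=tuple(
                PolyTerm(int(t["ph_pow"]), int(t["temp_pow"]), float(t["coef"]))
                for t in d["terms"]
            ),
            ph_domain=tuple(float(x) for x in d["domain"]["ph"]),
            temp_domain=tuple(float(x) for x in d["domain"]["temp_c"]),
            reference=(float(d["reference"]["ph"]), float(d["reference"]["temp_c"])),
            transform=d.get("transform", "log10"),
            provenance=d.get("provenance", ""),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "ActivitySurfaceModel":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class Prediction:
    """A single activity prediction.

    ``value`` is percent of optimum activity (non-negative, may exceed 100),
    ``log10_value`` its base-10 logarithm, and ``extrapolated`` is True iff
    the query point lay outside the model's validated domain.
    """

    value: float
    log10_value: float
    extrapolated: bool


def _check_finite(ph, temp) -> None:
    if not (np.all(np.isfinite(ph)) and np.all(np.isfinite(temp))):
        raise InvalidInputError("pH and temperature must be finite")


def evaluate_log10(model: ActivitySurfaceModel, ph, temp):
    """Evaluate the polynomial on the log10 scale.

    Accepts scalars or numpy arrays (broadcast together); returns the same
    shape.  This is a plain monomial sum — no domain checking or clipping.
    """
    _check_finite(ph, temp)
    ph = np.asarray(ph, dtype=float)
    temp = np.asarray(temp, dtype=float)
    out = np.zeros(np.broadcast(ph, temp).shape, dtype=float)
    for t in model.terms:
        out += t.coefficient * ph ** t.ph_power * temp ** t.temp_power
    return float(out) if out.ndim == 0 else out


def _reference_sanity(model: ActivitySurfaceModel) -> None:
    # A trustworthy %-of-optimum surface should predict within roughly an
    # order of magnitude of 100% at its own reference condition.  The printed
    # human equation predicts 10**31.6 % there.
    ref_log10 = evaluate_log10(model, *model.reference)
    if abs(ref_log10 - 2.0) > 1.0:
        warnings.warn(
            f"model ({model.species}, {model.variant}) predicts "
            f"10**{ref_log10:.4g} % at its own reference condition "
            f"{model.reference}; coefficients are likely mis-transcribed — "
            "prefer predict_relative() or a refit from data",
            CoefficientSanityWarning,
            stacklevel=3,
        )


def _apply_policy(model: ActivitySurfaceModel, ph: float, temp: float,
                  policy: ExtrapolationPolicy) -> bool:
    outside = not model.in_domain(ph, temp)
    if outside:
        bounds = []
        if not (model.ph_domain[0] <= ph <= model.ph_domain[1]):
            bounds.append(f"pH={ph} outside [{model.ph_domain[0]}, {model.ph_domain[1]}]")
        if not (model.temp_domain[0] <= temp <= model.temp_domain[1]):
            bounds.append(f"temp={temp} outside [{model.temp_domain[0]}, {model.temp_domain[1]}] degC")
        msg = "; ".join(bounds)
        if policy == "forbid":
            raise DomainBoundsError(msg)
        if policy == "warn":
            warnings.warn(f"extrapolating: {msg}", ExtrapolationWarning, stacklevel=3)
        elif policy != "allow":
            raise InvalidInputError(f"unknown extrapolation policy {policy!r}")
    return outside


def predict_activity(model: ActivitySurfaceModel, ph: float, temp: float,
                     policy: ExtrapolationPolicy = "warn") -> Prediction:
    """Predict absolute percent-of-optimum activity at one (pH, temp) point.

    ``policy`` controls behaviour outside the validated domain: ``"forbid"``
    raises :class:`DomainBoundsError` naming the violated bound, ``"warn"``
    (default) emits :class:`ExtrapolationWarning`, ``"allow"`` is silent.
    The returned value is ``10**log10`` and is never clipped at 100.
    """
    _check_finite(ph, temp)
    extrapolated = _apply_policy(model, float(ph), float(temp), policy)
    _reference_sanity(model)
    log10_value = evaluate_log10(model, float(ph), float(temp))
    return Prediction(value=10.0 ** log10_value, log10_value=log10_value,
                      extrapolated=extrapolated)


def predict_relative(model: ActivitySurfaceModel, ph: float, temp: float,
                     policy: ExtrapolationPolicy = "warn") -> float:
    """Activity as a percentage of the model's own reference-condition value.

    ``100 * 10**(L(ph, temp) - L(ph_ref, temp_ref))``; exactly 100 at the
    reference condition regardless of the surface's absolute calibration,
    which makes this the recommended output for surfaces (like the printed
    porcine equation) whose intercept-level calibration is off.
    """
    _check_finite(ph, temp)
    _apply_policy(model, float(ph), float(temp), policy)
    delta = evaluate_log10(model, float(ph), float(temp)) - evaluate_log10(model, *model.reference)
    return 100.0 * 10.0 ** delta


# ---------------------------------------------------------------------------
# Built-in published surfaces
# ---------------------------------------------------------------------------

# Human surface, 7 terms, coefficients exactly as published.  The
# temperature-linear coefficient 0.88912 is physically impossible (predicts
# 10**31.6 % at the optimum) and is presumed a misplaced decimal point.
_HUMAN_AS_PRINTED: dict[tuple[int, int], float] = {
    (0, 0): -0.17363,
    (1, 0): 0.76823,
    (0, 1): 0.88912,
    (1, 1): -0.02263,
    (2, 0): -0.08922,
    (0, 2): -0.00107,
    (1, 2): 0.00031,
}

# Porcine surface, 9 terms (adds pH^3 and temp^3), as published.  It
# evaluates to ~59.5% at the optimum; no single-coefficient amendment
# restores ~100%, so the corrected variant is coefficient-identical and
# predict_relative is the recommended output.
_PORCINE_AS_PRINTED: dict[tuple[int, int], float] = {
    (0, 0): -0.104906,
    (1, 0): 1.50841,
    (0, 1): 0.03685,
    (1, 1): -0.02088,
    (2, 0): -0.49262,
    (0, 2): 0.00071,
    (1, 2): 0.00045,
    (3, 0): 0.04129,
    (0, 3): -0.00003,
}

#: Editorial amendment applied by the human "corrected" variant.
HUMAN_TEMP_LINEAR_CORRECTED = 0.088912

BUILTIN_SPECIES = ("human", "porcine")
BUILTIN_VARIANTS = ("as_printed", "corrected")


def _terms_from(coefs: dict[tuple[int, int], float]) -> tuple[PolyTerm, ...]:
    return tuple(PolyTerm(p, q, c) for (p, q), c in coefs.items())


def builtin_model(species: str, variant: str = "corrected") -> ActivitySurfaceModel:
    """Return a built-in published surface.

    ``species`` is ``"human"`` or ``"porcine"``; ``variant`` is
    ``"as_printed"`` (coefficients exactly as published) or ``"corrected"``
    (documented editorial amendments only — see module docstring).
    """
    key = (species, variant)
    if species not in BUILTIN_SPECIES or variant not in BUILTIN_VARIANTS:
        raise ModelLookupError(
            f"no built-in model for {key!r}; species in {BUILTIN_SPECIES}, "
            f"variant in {BUILTIN_VARIANTS}"
        )
    if species == "human":
        coefs = dict(_HUMAN_AS_PRINTED)
        provenance = "published human pepsin equation, coefficients as printed"
        if variant == "corrected":
            coefs[(0, 1)] = HUMAN_TEMP_LINEAR_CORRECTED
            provenance = (
                "published human pepsin equation with editorial amendment: "
                "temperature-linear coefficient 0.88912 -> 0.088912 "
                "(restores ~100% prediction at the pH 2 / 37 degC optimum)"
            )
    else:
        coefs = dict(_PORCINE_AS_PRINTED)
        provenance = "published porcine pepsin equation, coefficients as printed"
        if variant == "corrected":
            provenance += (
                " (no amendment defined: no defensible single-coefficient fix "
                "exists; use predict_relative for normalised output)"
            )
    return ActivitySurfaceModel(species=species, variant=variant,
                                terms=_terms_from(coefs), provenance=provenance)


def intercept_only_model(log10_value: float, species: str = "custom") -> ActivitySurfaceModel:
    """A constant surface predicting ``10**log10_value`` everywhere (mostly a
    test and teaching aid)."""
    return ActivitySurfaceModel(
        species=species, variant="fitted",
        terms=(PolyTerm(0, 0, log10_value),),
        provenance="intercept-only constant surface",
    )
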