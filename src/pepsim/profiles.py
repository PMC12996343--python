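"""Gastric condition time series -> predicted activity profiles and AUC.

A :class:`DigestionProfile` is an ordered (time, pH, temperature) series
describing the conditions an enzyme experiences over an in vitro digestion;
:func:`activity_profile` maps it through an activity surface to an
:class:`ActivityProfile` with a trapezoidal area under the activity-time
curve (%·min), the cumulative proteolytic-capacity summary used to compare
digestion scenarios (e.g. static versus semi-dynamic protocols, or human
versus porcine enzyme on the same pH curve).

AUC is computed by the composite trapezoid rule on the native, possibly
irregular, grid — exact for piecewise-linear series and matching
spreadsheet-style calculation.  No gastric emptying or dilution happens
here; this module is a pure condition -> activity mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, InvalidInputError, ProfileRangeError
from .models import ActivitySurfaceModel, ExtrapolationPolicy, predict_activity, predict_relative

__all__ = [
    "DigestionTimepoint",
    "DigestionProfile",
    "ActivityProfile",
    "interpolate_conditions",
    "activity_profile",
    "compare_profiles",
    "ProfileComparison",
]


@dataclass(frozen=True)
class DigestionTimepoint:
    t_min: float
    ph: float
    temp: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.t_min, self.ph, self.temp])):
            raise InvalidInputError("timepoint fields must be finite")
        if self.t_min < 0:
            raise InvalidInputError("t_min must be >= 0")


@dataclass(frozen=True)
class DigestionProfile:
    """Ordered gastric condition series; times strictly increasing, at least
    two points."""

    label: str
    t_min: np.ndarray
    ph: np.ndarray
    temp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, float)
        ph = np.asarray(self.ph, float)
        temp = np.asarray(self.temp, float)
        if t.ndim != 1 or len(t) < 2 or len(ph) != len(t) or len(temp) != len(t):
            raise InvalidInputError("profile needs >= 2 timepoints with matching pH/temp arrays")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(ph)) or not np.all(np.isfinite(temp)):
            raise InvalidInputError("profile values must be finite")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("timepoints must be strictly increasing in t_min")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "temp", temp)

    @classmethod
    def from_timepoints(cls, label: str, timepoints) -> "DigestionProfile":
        tps = sorted(timepoints, key=lambda x: x.t_min)
        return cls(
            label=label,
            t_min=np.array([tp.t_min for tp in tps]),
            ph=np.array([tp.ph for tp in tps]),
            temp=np.array([tp.temp for tp in tps]),
        )

    @classmethod
    def constant(cls, label: str, duration_min: float, ph: float,
                 temp: float = 37.0) -> "DigestionProfile":
        """A static protocol: constant pH and temperature over [0, duration]."""
        return cls(label=label, t_min=np.array([0.0, float(duration_min)]),
                   ph=np.array([ph, ph]), temp=np.array([temp, temp]))

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "DigestionProfile":
        df = pd.read_csv(path)
        for col in ("t_min", "ph", "temp_c"):
            if col not in df.columns:
                raise InvalidInputError(f"profile CSV must have columns t_min,ph,temp_c (missing {col})")
        return cls(label=label or str(path), t_min=df["t_min"].to_numpy(float),
                   ph=df["ph"].to_numpy(float), temp=df["temp_c"].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.t_min, "ph": self.ph, "temp_c": self.temp})

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t_min[0]), float(self.t_min[-1])


def interpolate_conditions(profile: DigestionProfile, t: float) -> tuple[float, float]:
    """Piecewise-linear (pH, temp) at time ``t``; conditions are never
    extrapolated outside the profile span."""
    lo, hi = profile.span
    if not (lo <= t <= hi):
        raise ProfileRangeError(f"t={t} outside profile span [{lo}, {hi}] min")
    return (
        float(np.interp(t, profile.t_min, profile.ph)),
        float(np.interp(t, profile.t_min, profile.temp)),
    )


@dataclass(frozen=True)
class ActivityProfile:
    """Predicted activity over a digestion profile's native time grid."""

    label: str
    model_species: str
    model_variant: str
    relative: bool
    t_min: np.ndarray
    activity_percent: np.ndarray

    @property
    def auc(self) -> float:
        """Trapezoidal area under the activity curve, %·min."""
        return float(np.trapezoid(self.activity_percent, self.t_min))

    def to_frame(self, profile: DigestionProfile | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"t_min": self.t_min, "activity_percent": self.activity_percent})
        if profile is not None:
            df.insert(1, "ph", profile.ph)
            df.insert(2, "temp_c", profile.temp)
        return df


def activity_profile(model: ActivitySurfaceModel, profile: DigestionProfile,
                     relative: bool = True,
                     policy: ExtrapolationPolicy = "warn") -> ActivityProfile:
    """Predict activity at every timepoint of ``profile``.

    ``relative=True`` (default) uses :func:`predict_relative` — activity
    normalised to the surface's own reference-condition value; otherwise the
    surface's absolute percent-of-optimum prediction is used.  Domain
    violations follow ``policy``.
    """
    predict = predict_relative if relative else (
        lambda m, p, t, policy: predict_activity(m, p, t, policy).value
    )
    values = np.array([
        predict(model, float(p), float(tc), policy=policy)
        for p, tc in zip(profile.ph, profile.temp)
    ])
    return ActivityProfile(
        label=profile.label,
        model_species=model.species,
        model_variant=model.variant,
        relative=relative,
        t_min=profile.t_min.copy(),
        activity_percent=values,
    )


@dataclass(frozen=True)
class ProfileComparison:
    auc_a: float
    auc_b: float
    auc_ratio: float            # nan when auc_b == 0
    t_min: np.ndarray           # union grid over the overlapping time range
    difference: np.ndarray      # activity_a - activity_b on the union grid


def compare_profiles(a: ActivityProfile, b: ActivityProfile) -> ProfileComparison:
    """Compare two activity profiles over their overlapping time range.

    AUCs (and their ratio a/b) are computed over the overlap; pointwise
    differences are evaluated on the union of the two grids with linear
    interpolation.  A zero denominator AUC yields ratio NaN, not an error.
    """
    lo = max(a.t_min[0], b.t_min[0])
    hi = min(a.t_min[-1], b.t_min[-1])
    if lo >= hi:
        raise GridMismatchError(
            f"profiles do not overlap in time: [{a.t_min[0]}, {a.t_min[-1]}] vs "
            f"[{b.t_min[0]}, {b.t_min[-1]}]"
        )
    union = np.union1d(a.t_min, b.t_min)
    union = union[(union >= lo) & (union <= hi)]
    ya = np.interp(union, a.t_min, a.activity_percent)
    yb = np.interp(union, b.t_min, b.activity_percent)
    auc_a = float(np.trapezoid(ya, union))
    auc_b = float(np.trapezoid(yb, union))
    ratio = auc_a / auc_b if auc_b != 0 else float("nan")
    return ProfileComparison(auc_a=auc_a, auc_b=auc_b, auc_ratio=ratio,
                             t_min=union, difference=ya - yb)
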