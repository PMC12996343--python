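"""Thermal inactivation of porcine pepsin: retention table, minimal-treatment
decision rule, and a descriptive log-linear rate fit.

Measured residual activities after heating (percent of the pH 2 / 37 deg C
optimum, activity re-assayed at 37 deg C after cooling):

=========  ======  ======  ======
temp / t    5 min  10 min  15 min
=========  ======  ======  ======
65 deg C    95.35   72.37   45.21
>=75 degC    0.00    0.00    0.00
=========  ======  ======  ======

Any exposure of at least 5 min at 75 deg C or above irreversibly denatures
the enzyme; 15 min at 65 deg C does not.  The 65 deg C decay visibly
accelerates with time (not first-order), so the log-linear rate fit here is
a descriptive summary — report it with its R² and never extrapolate beyond
15 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .exceptions import InvalidInputError, NoFitError, ProfileRangeError

__all__ = [
    "HeatTreatmentRecord",
    "InactivationTable",
    "default_table",
    "ResidualActivity",
    "residual_activity",
    "is_irreversibly_inactivated",
    "RateFit",
    "fit_loglinear_rate",
    "INACTIVATION_TEMP_C",
    "INACTIVATION_MIN_DURATION_MIN",
]

#: Minimal validated irreversible-inactivation treatment: 75 deg C for 5 min.
INACTIVATION_TEMP_C = 75.0
INACTIVATION_MIN_DURATION_MIN = 5.0


@dataclass(frozen=True)
class HeatTreatmentRecord:
    temp: float               # deg C
    duration: float           # min
    residual_activity: float  # percent of optimum

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise InvalidInputError("duration must be >= 0")
        if self.residual_activity < 0:
            raise InvalidInputError("residual_activity must be >= 0")


_BUILTIN = {
    (65.0, 5.0): 95.35,
    (65.0, 10.0): 72.37,
    (65.0, 15.0): 45.21,
    **{(t, d): 0.0 for t in (75.0, 85.0, 95.0) for d in (5.0, 10.0, 15.0)},
}


@dataclass(frozen=True)
class InactivationTable:
    """Residual-activity records on a temperature x duration grid; residual
    activity must be non-increasing in duration at each temperature."""

    records: tuple[HeatTreatmentRecord, ...]

    def __post_init__(self) -> None:
        for temp in self.temperatures:
            rows = sorted((r for r in self.records if r.temp == temp),
                          key=lambda r: r.duration)
            residuals = [r.residual_activity for r in rows]
            if any(b > a + 1e-12 for a, b in zip(residuals, residuals[1:])):
                raise InvalidInputError(
                    f"residual activity increases with duration at {temp} degC"
                )

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted({r.temp for r in self.records}))

    @property
    def durations(self) -> tuple[float, ...]:
        return tuple(sorted({r.duration for r in self.records}))

    def at_temperature(self, temp: float) -> list[HeatTreatmentRecord]:
        return sorted((r for r in self.records if r.temp == temp),
                      key=lambda r: r.duration)

    def lookup(self, temp: float, duration: float) -> float | None:
        for r in self.records:
            if r.temp == temp and r.duration == duration:
                return r.residual_activity
        return None


def default_table() -> InactivationTable:
    """The built-in measured retention table (65-95 deg C x 5-15 min)."""
    return InactivationTable(
        records=tuple(
            HeatTreatmentRecord(t, d, v) for (t, d), v in sorted(_BUILTIN.items())
        )
    )


class ResidualActivity(NamedTuple):
    value: float        # percent of optimum
    interpolated: bool  # False only at exactly tabulated (temp, duration)


def residual_activity(table: InactivationTable, temp: float,
                      duration: float) -> ResidualActivity:
    """Residual activity after heating ``duration`` min at ``temp`` deg C.

    Exact at tabulated points.  At a tabulated temperature, untabulated
    durations are linearly interpolated.  Between tabulated temperatures the
    higher (lower-temperature) neighbouring value is returned — deliberately
    conservative, since under-estimating residual activity would produce
    false "inactivated" calls.  All interpolated answers are flagged.
    """
    temps = table.temperatures
    durs = table.durations
    if not (temps[0] <= temp <= temps[-1]):
        raise ProfileRangeError(f"temperature {temp} outside tabulated range [{temps[0]}, {temps[-1]}] degC")
    if not (durs[0] <= duration <= durs[-1]):
        raise ProfileRangeError(f"duration {duration} outside tabulated range [{durs[0]}, {durs[-1]}] min")

    def at_temp(t: float) -> tuple[float, bool]:
        exact = table.lookup(t, duration)
        if exact is not None:
            return exact, False
        rows = table.at_temperature(t)
        d = np.array([r.duration for r in rows])
        v = np.array([r.residual_activity for r in rows])
        return float(np.interp(duration, d, v)), True

    if temp in temps:
        value, interp = at_temp(temp)
        return ResidualActivity(value, interp)
    below = max(t for t in temps if t < temp)
    above = min(t for t in temps if t > temp)
    v_below, _ = at_temp(below)
    v_above, _ = at_temp(above)
    return ResidualActivity(max(v_below, v_above), True)


def is_irreversibly_inactivated(temp: float, duration: float) -> bool:
    """True iff the treatment is at least the minimal validated inactivation
    treatment (75 deg C for 5 min).  Deliberately conservative: shorter or
    cooler treatments return False even where inactivation is plausible."""
    return temp >= INACTIVATION_TEMP_C and duration >= INACTIVATION_MIN_DURATION_MIN


class RateFit(NamedTuple):
    k_per_min: float
    r_squared: float
    n_points: int


def fit_loglinear_rate(records: Iterable[HeatTreatmentRecord],
                       include_origin: bool = False) -> RateFit:
    """First-order summary rate: least-squares slope of ln(residual %) versus
    duration; returns k = -slope (per min) with the fit R².

    ``include_origin`` anchors the regression at (0 min, 100%).  Records with
    zero residual activity are excluded (their log is undefined); if fewer
    than two points remain there is nothing to fit.
    """
    pts = [(r.duration, r.residual_activity) for r in records if r.residual_activity > 0]
    if include_origin:
        pts = [(0.0, 100.0)] + pts
    if len(pts) < 2 or len({t for t, _ in pts}) < 2:
        raise NoFitError("need >= 2 records with positive residual activity at distinct durations")
    t = np.array([p[0] for p in pts])
    y = np.log(np.array([p[1] for p in pts]))
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return RateFit(k_per_min=float(-slope), r_squared=r2, n_points=len(pts))
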