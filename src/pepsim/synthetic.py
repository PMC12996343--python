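"""Seeded synthetic inputs for every other module.

Generates activity datasets from a known surface (log10-normal measurement
noise, matching the log-transformed fitting scale), gastric pH curves
(static, semi-dynamic exponential descent, or meal-response shapes), and
spectrophotometric assay readings by inverting the unit formula.  All
generators are pure functions of their :class:`GeneratorSpec` — identical
spec, identical output — so every downstream test and the acceptance script
run without any external data.

The "paper-like" 37-point design emulates the structure of the published
experiment — a D-optimal selection of 26 pH/temperature combinations over
pH 1-7 / 4-60 deg C plus 11 points sampled along a semi-dynamic digestion
trajectory — without claiming to equal the undisclosed original design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .assay import UNIT_DELTA_A280_PER_MIN, AssayReading
from .exceptions import InvalidInputError
from .fitting import NINE_TERM, ActivityDataset, ActivityObservation, doptimal_design
from .models import ActivitySurfaceModel, evaluate_log10
from .simulator import PHCurve

__all__ = [
    "GeneratorSpec",
    "paper_like_design",
    "generate_activity_dataset",
    "generate_ph_curve",
    "generate_assay_readings",
]

CurveKind = Literal["static", "semidynamic", "invivo_meal"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducible generator configuration.

    ``design`` may be an explicit list of (pH, temp) points or the name of a
    preset (``"paper_like_37"``).  ``noise_sd_log10`` is the SD of Gaussian
    noise added on the log10 activity scale (default 0.05 — large enough
    that recovery tests are meaningful, small enough that they are stable).
    """

    seed: int = 0
    noise_sd_log10: float = 0.05
    design: Sequence[tuple[float, float]] | str = "paper_like_37"
    curve_kind: CurveKind = "semidynamic"

    def __post_init__(self) -> None:
        if self.noise_sd_log10 < 0:
            raise InvalidInputError("noise_sd_log10 must be >= 0")


def paper_like_design(seed: int = 0) -> list[tuple[float, float]]:
    """A 37-point pH/temperature design: D-optimal 26-point selection for the
    9-term basis over a pH 1-7 x 4-60 deg C candidate grid, plus 11 points
    along a semi-dynamic trajectory (pH 6.5 -> 2 at 37 deg C)."""
    ph_levels = np.arange(1.0, 7.5, 0.5)
    temp_levels = np.array([4.0, 10.0, 15.0, 20.0, 25.0, 30.0, 37.0, 45.0, 52.0, 60.0])
    candidates = [(float(p), float(t)) for p in ph_levels for t in temp_levels]
    sel = doptimal_design(candidates, NINE_TERM, n_points=26, seed=seed)
    traj_t = np.linspace(0.0, 240.0, 11)
    traj_ph = _semidynamic_ph(traj_t, 240.0, 6.5, 2.0, rate=3.0)
    trajectory = [(float(round(p, 2)), 37.0) for p in traj_ph]
    return list(sel.points) + trajectory


def _resolve_design(spec: GeneratorSpec) -> list[tuple[float, float]]:
    if isinstance(spec.design, str):
        if spec.design != "paper_like_37":
            raise InvalidInputError(f"unknown design preset {spec.design!r}")
        return paper_like_design(seed=spec.seed)
    return [(float(p), float(t)) for p, t in spec.design]


def generate_activity_dataset(true_model: ActivitySurfaceModel,
                              spec: GeneratorSpec) -> ActivityDataset:
    """Activities ``10**(L(point) + eps)`` with ``eps ~ N(0, noise_sd_log10)``
    at the spec's design points; run_ids sequential from 1."""
    points = _resolve_design(spec)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd_log10, size=len(points)) \
        if spec.noise_sd_log10 > 0 else np.zeros(len(points))
    obs = []
    for i, ((ph, temp), e) in enumerate(zip(points, eps), start=1):
        log10_act = evaluate_log10(true_model, ph, temp) + e
        obs.append(ActivityObservation(run_id=i, ph=ph, temp=temp,
                                       activity=10.0 ** log10_act))
    return ActivityDataset(species=true_model.species, observations=obs)


def _semidynamic_ph(t: np.ndarray, duration: float, start_ph: float,
                    end_ph: float, rate: float) -> np.ndarray:
    # exponential approach from start to end, hitting end exactly at t=duration
    decay = np.exp(-rate * t / duration)
    floor = np.exp(-rate)
    shape = (decay - floor) / (1.0 - floor)
    return end_ph + (start_ph - end_ph) * shape


def generate_ph_curve(spec: GeneratorSpec, duration: float, start_ph: float,
                      end_ph: float = 2.0, n_anchors: int = 49) -> PHCurve:
    """A gastric pH curve of the spec's ``curve_kind``.

    ``static``: constant ``start_ph``.  ``semidynamic``: strictly monotone
    exponential-approach descent from ``start_ph`` to exactly ``end_ph`` at
    ``duration`` (descent rate jittered +/-20% by the seed).  ``invivo_meal``:
    a postprandial shape — plateau near ``start_ph`` for the first ~15% of
    the window, then the same exponential descent.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be > 0")
    t = np.linspace(0.0, float(duration), max(2, int(n_anchors)))
    rng = np.random.default_rng(spec.seed)
    if spec.curve_kind == "static":
        ph = np.full_like(t, float(start_ph))
    elif spec.curve_kind == "semidynamic":
        rate = 3.0 * (1.0 + 0.2 * (2.0 * rng.random() - 1.0))
        ph = _semidynamic_ph(t, duration, start_ph, end_ph, rate)
    elif spec.curve_kind == "invivo_meal":
        rate = 3.0 * (1.0 + 0.2 * (2.0 * rng.random() - 1.0))
        t_plateau = 0.15 * duration
        ph = np.where(
            t <= t_plateau,
            float(start_ph),
            _semidynamic_ph(np.maximum(t - t_plateau, 0.0), duration - t_plateau,
                            start_ph, end_ph, rate),
        )
    else:
        raise InvalidInputError(f"unknown curve_kind {spec.curve_kind!r}")
    return PHCurve(t_min=t, ph=ph)


def generate_assay_readings(true_u_per_mL: float, n: int, noise_sd: float,
                            spec: GeneratorSpec,
                            incubation_min: float = 10.0,
                            enzyme_volume_mL: float = 0.1,
                            dilution_factor: float = 1.0,
                            blank_a280: float = 0.05) -> list[AssayReading]:
    """Readings whose noise-free ΔA280 inverts the unit formula exactly:
    ``ΔA = u * volume / dilution * 0.001 * minutes``, plus seeded Gaussian
    absorbance noise on the sample reading."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if true_u_per_mL < 0 or noise_sd < 0:
        raise InvalidInputError("true activity and noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed)
    delta = (true_u_per_mL * enzyme_volume_mL / dilution_factor
             * UNIT_DELTA_A280_PER_MIN * incubation_min)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    return [
        AssayReading(
            a280_sample=blank_a280 + delta + e,
            a280_blank=blank_a280,
            incubation_min=incubation_min,
            enzyme_volume_mL=enzyme_volume_mL,
            dilution_factor=dilution_factor,
        )
        for e in noise
    ]
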