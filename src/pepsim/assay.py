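"""INFOGEST pepsin unit arithmetic from spectrophotometric readings.

One pepsin unit (U) produces a ΔA280 of 0.001 per minute at pH 2.0 and
37 deg C, measured as TCA-soluble products of haemoglobin digestion.  The
published assay reports U per mL of enzyme solution added to the reaction,
so the unit calculation divides by the enzyme aliquot volume; powdered
enzymes are additionally reported per mg via their solution concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "AssayReading",
    "UNIT_DELTA_A280_PER_MIN",
    "units_per_mL",
    "units_per_mg",
    "percent_of_optimum",
    "read_assay_csv",
    "units_table",
]

#: ΔA280 per minute produced by one unit, by definition.
UNIT_DELTA_A280_PER_MIN = 0.001


@dataclass(frozen=True)
class AssayReading:
    """One spectrophotometric reading pair with its assay geometry."""

    a280_sample: float
    a280_blank: float
    incubation_min: float
    enzyme_volume_mL: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.incubation_min <= 0:
            raise InvalidInputError("incubation_min must be > 0")
        if self.enzyme_volume_mL <= 0:
            raise InvalidInputError("enzyme_volume_mL must be > 0")
        if self.dilution_factor < 1:
            raise InvalidInputError("dilution_factor must be >= 1")


def units_per_mL(reading: AssayReading) -> float:
    """Activity in U per mL of enzyme solution added.

    ``((A_sample - A_blank) / minutes / 0.001) * dilution / volume_mL``.
    A blank exceeding the sample (possible by noise) clamps ΔA to 0 with a
    warning rather than producing a negative activity.
    """
    delta = reading.a280_sample - reading.a280_blank
    if delta < 0:
        warnings.warn(
            f"blank absorbance exceeds sample by {-delta:.4g}; clamping ΔA280 to 0",
            UserWarning, stacklevel=2,
        )
        delta = 0.0
    units = delta / reading.incubation_min / UNIT_DELTA_A280_PER_MIN
    return units * reading.dilution_factor / reading.enzyme_volume_mL


def units_per_mg(u_per_mL: float, enzyme_conc_mg_per_mL: float) -> float:
    """Convert U/mL of enzyme solution to U/mg of enzyme powder."""
    if enzyme_conc_mg_per_mL <= 0:
        raise InvalidInputError("enzyme concentration must be > 0")
    return u_per_mL / enzyme_conc_mg_per_mL


def percent_of_optimum(activity: float, optimum: float) -> float:
    """Activity as a percentage of the optimum-condition activity; values
    above 100 are legitimate and returned as-is."""
    if optimum <= 0:
        raise InvalidInputError("optimum activity must be > 0")
    return 100.0 * activity / optimum


_CSV_COLUMNS = ["sample_id", "a280_sample", "a280_blank", "incubation_min",
                "enzyme_volume_mL", "dilution_factor"]


def read_assay_csv(path) -> list[tuple[str, AssayReading]]:
    """Read plate/cuvette exports with columns
    ``sample_id,a280_sample,a280_blank,incubation_min,enzyme_volume_mL,dilution_factor``
    (dilution_factor optional, default 1)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise InvalidInputError(f"assay CSV missing columns: {missing}")
    if "dilution_factor" not in df.columns:
        df["dilution_factor"] = 1.0
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                str(row["sample_id"]),
                AssayReading(
                    a280_sample=float(row["a280_sample"]),
                    a280_blank=float(row["a280_blank"]),
                    incubation_min=float(row["incubation_min"]),
                    enzyme_volume_mL=float(row["enzyme_volume_mL"]),
                    dilution_factor=float(row["dilution_factor"]),
                ),
            )
        )
    return out


def units_table(path) -> pd.DataFrame:
    """Per-sample activity table (sample_id, u_per_ml) from an assay CSV."""
    rows = [(sid, units_per_mL(r)) for sid, r in read_assay_csv(path)]
    return pd.DataFrame(rows, columns=["sample_id", "u_per_ml"])
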