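"""Clinical functional parameters of LV performance.

Volumes enter in mL at the API surface (1 mL = 1000 mm^3); mass uses the
standard myocardial density of 1.05 g/mL and is indexed to body surface area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class SubjectRecord:
    """Demographics, functional parameters and outcome for one subject."""

    subject_id: str
    age: float            # years
    sex: str              # "M" or "F"
    bsa: float            # m^2
    heart_rate: float     # beats/min
    systolic_pressure: float   # mmHg
    diastolic_pressure: float  # mmHg
    edv: float            # mL
    esv: float            # mL
    event: int            # 1 = complicated (valve repair/replacement)
    lv_mass: float | None = None  # g
    group: str = "none"   # none / moderate / severe

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.edv > self.esv >= 0:
            raise ValidationError("EDV must exceed ESV >= 0")
        if self.bsa <= 0:
            raise ValidationError("BSA must be positive")
        if self.heart_rate <= 0:
            raise ValidationError("heart rate must be positive")
        if self.systolic_pressure <= 0 or self.diastolic_pressure <= 0:
            raise ValidationError("pressures must be positive")
        if self.event not in (0, 1):
            raise ValidationError("event must be binary (0/1)")


def stroke_volume(edv: float, esv: float) -> float:
    """SV = EDV - ESV (mL)."""
    if edv <= 0:
        raise ValidationError("EDV must be positive")
    if not edv > esv >= 0:
        raise ValidationError("require EDV > ESV >= 0")
    return edv - esv


def ejection_fraction(edv: float, esv: float) -> float:
    """EF = 100 * SV / EDV (%)."""
    return 100.0 * stroke_volume(edv, esv) / edv


def cardiac_output(sv: float, heart_rate: float) -> float:
    """CO = SV * HR (mL/min)."""
    if sv <= 0:
        raise ValidationError("stroke volume must be positive")
    if heart_rate <= 0:
        raise ValidationError("heart rate must be positive")
    return sv * heart_rate


def lv_mass_index(endo_volume_mm3: float, epi_volume_mm3: float,
                  bsa: float) -> float:
    """LV mass index (g/m^2) from cavity and epicardial volumes.

    Myocardial volume = epi - endo (mm^3); mass = volume/1000 x 1.05 g/mL;
    LVMI = mass / BSA.
    """
    if bsa <= 0:
        raise ValidationError("BSA must be positive")
    wall = epi_volume_mm3 - endo_volume_mm3
    if wall <= 0:
        raise ValidationError("epicardial volume must exceed cavity volume")
    mass_g = wall / 1000.0 * MYOCARDIAL_DENSITY_G_PER_ML
    return mass_g / bsa


def mean_arterial_pressure(systolic: float, diastolic: float) -> float:
    """MAP = DP + (SP - DP)/3 (mmHg)."""
    if systolic <= diastolic:
        raise ValidationError("systolic pressure must exceed diastolic")
    return diastolic + (systolic - diastolic) / 3.0


def add_derived_metrics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns (sv, ef, co, map) to a cohort table.

    Requires columns edv, esv, heart_rate, systolic_pressure,
    diastolic_pressure.
    """
    out = cohort.copy()
    if not (out["edv"] > out["esv"]).all():
        raise ValidationError("every row must satisfy EDV > ESV")
    out["sv"] = out["edv"] - out["esv"]
    out["ef"] = 100.0 * out["sv"] / out["edv"]
    out["co"] = out["sv"] * out["heart_rate"]
    out["map"] = out["diastolic_pressure"] + (
        out["systolic_pressure"] - out["diastolic_pressure"]) / 3.0
    return out


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV and validate the SubjectRecord columns."""
    df = pd.read_csv(path)
    required = ["subject_id", "age", "sex", "bsa", "heart_rate",
                "systolic_pressure", "diastolic_pressure", "edv", "esv",
                "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table is missing columns: {missing}")
    if not (df["edv"] > df["esv"]).all():
        raise ValidationError("cohort contains rows with ESV >= EDV")
    return df


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    cohort.to_csv(path, index=False)
    return Path(path)
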