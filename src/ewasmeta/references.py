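"""Growth references: LMS tables and IOTF-style BMI cutoff tables.

The package ships coarse synthetic reference tables (both sexes, ages
2-18 y) so the full pipeline runs without any external download.  Real
references in the same CSV layout can be supplied by file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LMSReference",
    "IOTFCutoffs",
    "load_synthetic_lms",
    "load_synthetic_iotf",
]


class ReferenceRangeError(ValueError):
    """Requested age (or sex) falls outside the reference grid."""


def _check_sex_age_table(table: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    sexes = set(table["sex"].unique())
    if not {"F", "M"} <= sexes:
        raise ValueError(f"{name}: both sexes 'F' and 'M' must be present, got {sorted(sexes)}")
    for sex, grp in table.groupby("sex"):
        ages = grp["age_years"].to_numpy()
        if not np.all(np.diff(ages) > 0):
            raise ValueError(f"{name}: ages must be strictly increasing within sex {sex!r}")


def _interp_columns(
    table: pd.DataFrame, sex: np.ndarray, age: np.ndarray, columns: list[str], name: str
) -> list[np.ndarray]:
    """Linear age-interpolation of reference columns at each (sex, age)."""
    sex = np.asarray(sex, dtype=object)
    age = np.asarray(age, dtype=float)
    out = [np.empty(age.shape, dtype=float) for _ in columns]
    for s in np.unique(sex):
        grp = table[table["sex"] == s]
        if grp.empty:
            raise ReferenceRangeError(f"{name}: sex {s!r} absent from reference")
        mask = sex == s
        a = age[mask]
        grid = grp["age_years"].to_numpy()
        if np.any(a < grid[0]) or np.any(a > grid[-1]):
            raise ReferenceRangeError(
                f"{name}: age outside reference range [{grid[0]}, {grid[-1]}] for sex {s!r}"
            )
        for j, col in enumerate(columns):
            out[j][mask] = np.interp(a, grid, grp[col].to_numpy())
    return out


@dataclass(frozen=True)
class LMSReference:
    """Sex- and age-indexed L (power), M (median), S (coefficient of variation)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_sex_age_table(self.table, ["sex", "age_years", "L", "M", "S"], "LMSReference")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("LMSReference: M and S must be positive")

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def lookup(self, sex, age):
        """Interpolated (L, M, S) arrays at each (sex, age)."""
        return _interp_columns(self.table, sex, age, ["L", "M", "S"], "LMSReference")

    @property
    def age_range(self) -> tuple[float, float]:
        by_sex = self.table.groupby("sex")["age_years"]
        return float(by_sex.min().max()), float(by_sex.max().min())


@dataclass(frozen=True)
class IOTFCutoffs:
    """Age/sex BMI thresholds for underweight, overweight, obesity (kg/m2)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["sex", "age_years", "bmi_underweight", "bmi_overweight", "bmi_obesity"]
        _check_sex_age_table(self.table, cols, "IOTFCutoffs")
        t = self.table
        ordered = (t["bmi_underweight"] < t["bmi_overweight"]) & (
            t["bmi_overweight"] < t["bmi_obesity"]
        )
        if not ordered.all():
            raise ValueError("IOTFCutoffs: require underweight < overweight < obesity per row")

    @classmethod
    def from_csv(cls, path) -> "IOTFCutoffs":
        return cls(pd.read_csv(path))

    def lookup(self, sex, age):
        """Interpolated (underweight, overweight, obesity) cutoffs."""
        return _interp_columns(
            self.table,
            sex,
            age,
            ["bmi_underweight", "bmi_overweight", "bmi_obesity"],
            "IOTFCutoffs",
        )


def _data_path(filename: str):
    return resources.files("ewasmeta").joinpath("data", filename)


def load_synthetic_lms() -> LMSReference:
    """Packaged synthetic LMS reference (not a published growth standard)."""
    with resources.as_file(_data_path("lms_reference_synthetic.csv")) as p:
        return LMSReference.from_csv(p)


def load_synthetic_iotf() -> IOTFCutoffs:
    """Packaged synthetic cutoff table in the IOTF layout (not the published IOTF values)."""
    with resources.as_file(_data_path("iotf_cutoffs_synthetic.csv")) as p:
        return IOTFCutoffs.from_csv(p)
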