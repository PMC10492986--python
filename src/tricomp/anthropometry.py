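"""Anthropometric indices: BMI, Haycock body surface area, LMS z-scores,
and weight-status classification.

The LMS machinery is reference-agnostic: any table of (sex, age) ->
(L, M, S) rows per measure can be supplied as a CSV with columns
``measure, sex, age_years, L, M, S``.  The package bundles a synthetic
reference for testing; published growth references (WHO BMI-for-age, waist
and waist:height references) drop in with no code change.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Biometrics",
    "LmsReference",
    "AnthroResult",
    "bmi",
    "bsa_haycock",
    "lms_zscore",
    "lms_inverse",
    "classify_weight_status",
    "bundled_reference",
    "augment_cohort",
]

# Haycock power-law coefficients: BSA[m^2] = c * W[kg]^p * H[cm]^q
_HAYCOCK_C = 0.024265
_HAYCOCK_PW = 0.5378
_HAYCOCK_PH = 0.3964


@dataclass(frozen=True)
class Biometrics:
    height_cm: float
    weight_kg: float
    waist_cm: float
    age_years: float
    sex: str  # "female" | "male"

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")
        if not 0 < self.age_years < 25:
            raise ValueError("age must lie in (0, 25) years")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


@dataclass(frozen=True)
class AnthroResult:
    bmi: float
    bsa: float
    bmi_z: float
    waist_z: float
    waist_height_z: float
    weight_status: str


def bmi(height_cm: float, weight_kg: float) -> float:
    """Body mass index, kg/m^2."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    h_m = height_cm / 100.0
    return weight_kg / (h_m * h_m)


def bsa_haycock(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Haycock power law."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return _HAYCOCK_C * weight_kg**_HAYCOCK_PW * height_cm**_HAYCOCK_PH


class LmsReference:
    """Age/sex-interpolated L, M, S lookup for one or more measures."""

    def __init__(self, table: pd.DataFrame, provenance: str = "unspecified"):
        required = {"measure", "sex", "age_years", "L", "M", "S"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("M and S must be positive")
        table = table.sort_values(["measure", "sex", "age_years"])
        for (measure, sex), grp in table.groupby(["measure", "sex"]):
            ages = grp["age_years"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise ValueError(
                    f"ages must be strictly increasing for {measure}/{sex}"
                )
        self.table = table.reset_index(drop=True)
        self.provenance = provenance

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "LmsReference":
        return cls(pd.read_csv(path), provenance or str(path))

    def measures(self) -> list[str]:
        return sorted(self.table["measure"].unique())

    def lookup(self, measure: str, sex: str, age_years: float) -> tuple[float, float, float]:
        """L, M, S at an age, linearly interpolated between tabulated rows."""
        grp = self.table[(self.table["measure"] == measure) & (self.table["sex"] == sex)]
        if grp.empty:
            raise KeyError(f"no LMS rows for measure={measure!r}, sex={sex!r}")
        ages = grp["age_years"].to_numpy()
        lo, hi = ages[0], ages[-1]
        if not lo <= age_years <= hi:
            raise ValueError(
                f"age {age_years} outside reference span [{lo}, {hi}] "
                f"for {measure}/{sex}"
            )
        out = tuple(
            float(np.interp(age_years, ages, grp[col].to_numpy()))
            for col in ("L", "M", "S")
        )
        return out


def lms_zscore(
    value: float, age_years: float, sex: str, reference: LmsReference, measure: str
) -> float:
    """LMS z-score: ((x/M)^L - 1) / (L*S), with the log-limit at L = 0."""
    if value <= 0:
        raise ValueError("value must be positive")
    L, M, S = reference.lookup(measure, sex, age_years)
    if abs(L) < 1e-12:
        return float(np.log(value / M) / S)
    return float(((value / M) ** L - 1.0) / (L * S))


def lms_inverse(
    z: float, age_years: float, sex: str, reference: LmsReference, measure: str
) -> float:
    """Invert the LMS transform: the value whose z-score is ``z``."""
    L, M, S = reference.lookup(measure, sex, age_years)
    if abs(L) < 1e-12:
        return float(M * np.exp(S * z))
    return float(M * (1.0 + L * S * z) ** (1.0 / L))


def classify_weight_status(bmi_z: float) -> str:
    """Two-group classification on the BMI z-score.

    > 1 -> overweight/obese; > -2 and <= 1 -> normal; <= -2 -> out-of-range
    (flagged, excluded from two-group comparisons).
    """
    if not np.isfinite(bmi_z):
        raise ValueError("bmi_z must be finite")
    if bmi_z > 1.0:
        return "overweight/obese"
    if bmi_z > -2.0:
        return "normal"
    return "underweight/out-of-range"


def bundled_reference() -> LmsReference:
    """The synthetic LMS reference shipped with the package (testing only)."""
    path = resources.files("tricomp.data").joinpath("lms_reference.csv")
    with resources.as_file(path) as p:
        return LmsReference.from_csv(p, provenance="tricomp bundled synthetic")


def augment_cohort(
    cohort: pd.DataFrame, reference: LmsReference | None = None
) -> pd.DataFrame:
    """Add bmi, bsa, z-score, and weight-status columns to a cohort table.

    Expects columns height_cm, weight_kg, waist_cm, age, sex (0 = female,
    1 = male).  Ages are clipped to the reference span before lookup so a
    simulated subject a few months outside the table does not abort a run.
    """
    ref = reference or bundled_reference()
    out = cohort.copy()
    sexes = np.where(out["sex"].to_numpy() == 1, "male", "female")
    spans: dict[tuple[str, str], tuple[float, float]] = {}
    for measure in ("bmi", "waist", "waist_height"):
        for sex in ("female", "male"):
            grp = ref.table[(ref.table["measure"] == measure) & (ref.table["sex"] == sex)]
            ages = grp["age_years"].to_numpy()
            spans[(measure, sex)] = (float(ages[0]), float(ages[-1]))

    bmis, bsas, bmi_z, waist_z, wh_z = [], [], [], [], []
    for h, w, wa, age, sex in zip(
        out["height_cm"], out["weight_kg"], out["waist_cm"], out["age"], sexes
    ):
        bmis.append(bmi(h, w))
        bsas.append(bsa_haycock(h, w))
        vals = {"bmi": bmis[-1], "waist": wa, "waist_height": wa / h}
        zs = {}
        for measure, val in vals.items():
            lo, hi = spans[(measure, sex)]
            zs[measure] = lms_zscore(val, float(np.clip(age, lo, hi)), sex, ref, measure)
        bmi_z.append(zs["bmi"])
        waist_z.append(zs["waist"])
        wh_z.append(zs["waist_height"])

    out["bmi"] = bmis
    out["bsa"] = bsas
    out["bmi_z"] = bmi_z
    out["waist_z"] = waist_z
    out["waist_height_z"] = wh_z
    out["weight_status"] = [classify_weight_status(z) for z in out["bmi_z"]]
    return out
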