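"""Synthetic phantoms, flow/area waveforms, and cohort tables with ground truth.

Every generator is fully seeded and returns both the data object and the
ground truth used to build it, so downstream stages can be tested without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from tricomp.segmentation import FatFractionStack

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "WaveformSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_waveform",
    "generate_cohort",
    "default_effects",
    "COHORT_OUTCOMES",
    "COHORT_PREDICTORS",
]


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic trunk cross-section stack.

    The body is an ellipse with a subcutaneous fat ring of configurable
    thickness.  The ring's inner boundary may be modulated by lobes
    (non-convex) and a left/right thickness gradient to stress radial
    boundary tracing.  VAT appears as circular blobs strictly inside the
    inner boundary.
    """

    slice_count: int = 4
    image_size: int = 128
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 10.0)  # mm (x, y, z)
    outer_semiaxes: tuple[float, float] = (150.0, 110.0)  # mm (a along x, b along y)
    sat_thickness: float = 30.0  # mm
    thickness_gradient: float = 0.0  # fractional cos(theta) modulation of thickness
    lobe_amplitude: float = 0.0  # fractional lobing of the inner boundary
    lobe_count: int = 0
    vat_blobs: tuple[tuple[float, float, float, float], ...] = ()  # (cx, cy, r) mm + ff
    body_fat_fraction: float = 0.10
    sat_fat_fraction: float = 0.85
    background_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.slice_count < 1 or self.image_size < 8:
            raise ValueError("slice_count >= 1 and image_size >= 8 required")
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        if self.sat_thickness <= 0:
            raise ValueError("sat_thickness must be > 0")
        a, b = self.outer_semiaxes
        if a <= 0 or b <= 0:
            raise ValueError("outer_semiaxes must be positive")
        half_x = self.image_size * self.voxel_dims[0] / 2.0
        half_y = self.image_size * self.voxel_dims[1] / 2.0
        if a >= half_x or b >= half_y:
            raise ValueError("body ellipse does not fit inside the image")
        for ff in (self.body_fat_fraction, self.sat_fat_fraction):
            if not 0.0 <= ff <= 1.0:
                raise ValueError("fat fractions must lie in [0, 1]")
        if abs(self.thickness_gradient) >= 1.0 or self.lobe_amplitude < 0:
            raise ValueError("thickness_gradient in (-1, 1); lobe_amplitude >= 0")
        for cx, cy, r, ff in self.vat_blobs:
            if r <= 0:
                raise ValueError("vat blob radius must be positive")
            if not 0.0 <= ff <= 1.0:
                raise ValueError("vat blob fat fraction must lie in [0, 1]")
            # blob must sit strictly inside the inner boundary (checked at
            # the blob's angular position, with the blob radius as margin)
            theta = np.arctan2(cy, cx)
            r_in = self._inner_radius(np.array([theta]))[0]
            if np.hypot(cx, cy) + r >= r_in:
                raise ValueError(
                    f"vat blob at ({cx}, {cy}) r={r} not strictly inside inner boundary"
                )

    # polar radius of the outer ellipse at angle theta
    def _outer_radius(self, theta: np.ndarray) -> np.ndarray:
        a, b = self.outer_semiaxes
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    def _thickness(self, theta: np.ndarray) -> np.ndarray:
        t = self.sat_thickness * (1.0 + self.thickness_gradient * np.cos(theta))
        if self.lobe_count > 0 and self.lobe_amplitude > 0:
            t = t * (1.0 + self.lobe_amplitude * np.cos(self.lobe_count * theta))
        return t

    def _inner_radius(self, theta: np.ndarray) -> np.ndarray:
        r = self._outer_radius(theta) - self._thickness(theta)
        return np.maximum(r, 0.0)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks and mask-counted volumes for a generated phantom."""

    tissue_mask: np.ndarray  # (slices, ny, nx) bool
    sat_mask: np.ndarray
    vat_mask: np.ndarray
    sat_volume_l: float
    vat_volume_l: float
    nat_volume_l: float
    total_tissue_volume_l: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sat_volume_l": self.sat_volume_l,
            "vat_volume_l": self.vat_volume_l,
            "nat_volume_l": self.nat_volume_l,
            "total_tissue_volume_l": self.total_tissue_volume_l,
        }


def generate_phantom(spec: PhantomSpec) -> tuple[FatFractionStack, PhantomTruth]:
    """Rasterize the phantom and return the image stack plus mask ground truth.

    Ground-truth volumes are counted from the drawn masks (pixel count x
    voxel volume), never from the analytic formulas, so segmentation
    recovery error reflects the algorithm rather than rasterization.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    dx, dy, dz = spec.voxel_dims
    # physical coordinates of pixel centers relative to the image center
    cx = (n - 1) / 2.0
    cy = (n - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    x = (cols - cx) * dx
    y = (rows - cy) * dy
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    r_out = spec._outer_radius(theta)
    r_in = spec._inner_radius(theta)
    tissue2d = r <= r_out
    sat2d = tissue2d & (r > r_in)
    vat2d = np.zeros_like(tissue2d)

    ff2d = np.where(tissue2d, spec.body_fat_fraction, 0.0)
    ff2d[sat2d] = spec.sat_fat_fraction
    for bx, by, br, bff in spec.vat_blobs:
        blob = np.hypot(x - bx, y - by) <= br
        vat2d |= blob
        ff2d[blob] = bff
    combined2d = tissue2d.astype(float)

    nslc = spec.slice_count
    ff = np.repeat(ff2d[None], nslc, axis=0)
    combined = np.repeat(combined2d[None], nslc, axis=0)
    if spec.background_noise_sd > 0:
        ff = ff + rng.normal(0.0, spec.background_noise_sd, size=ff.shape)
        combined = combined + rng.normal(0.0, spec.background_noise_sd, size=combined.shape)
    ff = np.clip(ff, 0.0, 1.0)

    stack = FatFractionStack(
        fat_fraction=ff,
        combined_signal=combined,
        voxel_dims=spec.voxel_dims,
        slab_convention="neck-to-knees, arms excluded",
    )

    voxvol_l = dx * dy * dz / 1e6  # mm^3 -> L
    tissue_mask = np.repeat(tissue2d[None], nslc, axis=0)
    sat_mask = np.repeat(sat2d[None], nslc, axis=0)
    vat_mask = np.repeat(vat2d[None], nslc, axis=0)
    sat_v = float(sat_mask.sum() * voxvol_l)
    vat_v = float(vat_mask.sum() * voxvol_l)
    tot_v = float(tissue_mask.sum() * voxvol_l)
    truth = PhantomTruth(
        tissue_mask=tissue_mask,
        sat_mask=sat_mask,
        vat_mask=vat_mask,
        sat_volume_l=sat_v,
        vat_volume_l=vat_v,
        nat_volume_l=tot_v - sat_v - vat_v,
        total_tissue_volume_l=tot_v,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformSpec:
    """Aortic flow/area waveform with a known flow-area slope.

    Pre-reflection, the lumen area obeys A(t) = A0 + Q(t) / true_pwv with Q
    in mL/s and A in mm^2, so the flow-area slope in those units *is* the
    wave speed in m/s (1 mL/s per mm^2 = 1000 mm/s).  After
    ``reflection_onset`` of systole an additive area bump breaks that
    linearity, emulating wave reflection.
    """

    true_pwv: float = 4.0  # m/s
    baseline_area: float = 500.0  # mm^2
    peak_flow: float = 400.0  # mL/s
    sample_interval: float = 9.6  # ms
    cycle_duration: float = 800.0  # ms
    systole_duration: float = 300.0  # ms
    foot_delay: float = 40.0  # ms from R-wave to upstroke foot
    reflection_onset: float = 0.6  # fraction of systole
    reflection_amplitude: float = 0.25  # fraction of the peak area excursion
    noise_sd: float | tuple[float, float] = 0.0  # fraction of each channel's range
    seed: int = 0

    def validate(self) -> None:
        if self.true_pwv <= 0:
            raise ValueError("true_pwv must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if not 0.0 < self.reflection_onset <= 1.0:
            raise ValueError("reflection_onset must lie in (0, 1]")
        if self.peak_flow <= 0 or self.baseline_area <= 0:
            raise ValueError("peak_flow and baseline_area must be positive")
        if self.systole_duration + self.foot_delay >= self.cycle_duration:
            raise ValueError("systole + foot delay must fit inside the cycle")

    @property
    def noise_pair(self) -> tuple[float, float]:
        if isinstance(self.noise_sd, tuple):
            return self.noise_sd
        return (float(self.noise_sd), float(self.noise_sd))


def generate_waveform(spec: WaveformSpec) -> tuple[pd.DataFrame, float]:
    """Return (waveform frame with columns t_ms/Q_ml_s/A_mm2, true PWV)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.cycle_duration, spec.sample_interval)
    phase = (t - spec.foot_delay) / spec.systole_duration
    q = np.where(
        (phase >= 0.0) & (phase <= 1.0),
        spec.peak_flow * np.sin(np.pi * np.clip(phase, 0.0, 1.0)),
        0.0,
    )
    a = spec.baseline_area + q / spec.true_pwv

    # reflected wave: additive late-systolic area bump, absent when the
    # whole systole is declared reflection-free
    if spec.reflection_onset < 1.0 and spec.reflection_amplitude > 0:
        t_refl = spec.foot_delay + spec.reflection_onset * spec.systole_duration
        width = 0.15 * spec.systole_duration
        bump = (
            spec.reflection_amplitude
            * (spec.peak_flow / spec.true_pwv)
            * np.exp(-0.5 * ((t - t_refl - width) / width) ** 2)
        )
        bump[t < t_refl] = 0.0
        a = a + bump

    q_sd, a_sd = spec.noise_pair
    if q_sd > 0:
        q = q + rng.normal(0.0, q_sd * spec.peak_flow, size=q.size)
    if a_sd > 0:
        a_range = spec.peak_flow / spec.true_pwv
        a = a + rng.normal(0.0, a_sd * a_range, size=a.size)

    frame = pd.DataFrame({"t_ms": t, "Q_ml_s": q, "A_mm2": a})
    return frame, spec.true_pwv


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

COHORT_PREDICTORS = ("nat", "sat", "vat", "age", "sex")

COHORT_OUTCOMES = (
    "sbp", "dbp", "mbp", "pulse_pressure", "svr", "co", "sv", "heart_rate",
    "lvedv", "lvef", "lv_mass", "mass_to_edv", "e_a", "septal_ea",
    "lateral_ea", "pwv_aao", "pwv_dao", "tac",
)

# location/scale used to place standardized outcomes on physiological scales
_OUTCOME_SCALE: dict[str, tuple[float, float]] = {
    "sbp": (113.0, 8.0), "dbp": (59.0, 5.0), "mbp": (82.0, 6.0),
    "pulse_pressure": (52.0, 7.0), "svr": (14.0, 2.0), "co": (5.9, 0.9),
    "sv": (88.0, 13.0), "heart_rate": (68.0, 9.0), "lvedv": (147.0, 20.0),
    "lvef": (62.0, 3.0), "lv_mass": (110.0, 25.0), "mass_to_edv": (0.78, 0.08),
    "e_a": (1.75, 0.30), "septal_ea": (2.10, 0.40), "lateral_ea": (2.80, 0.50),
    "pwv_aao": (4.2, 0.9), "pwv_dao": (3.9, 0.9), "tac": (1.65, 0.25),
}


def default_effects() -> pd.DataFrame:
    """A qualitative default effect matrix: NAT drives cardiac size and
    systolic load, SAT drives diastolic ratios, heart rate and resistance;
    VAT carries no independent effect.  Values are design choices for the
    simulator, not estimates of anything.
    """
    eff = pd.DataFrame(0.0, index=list(COHORT_OUTCOMES), columns=list(COHORT_PREDICTORS))
    eff.loc["lv_mass", "nat"] = 0.8
    eff.loc["lvedv", "nat"] = 0.7
    eff.loc["sv", "nat"] = 0.6
    eff.loc["sbp", "nat"] = 0.35
    eff.loc["pulse_pressure", "nat"] = 0.45
    eff.loc["mass_to_edv", "nat"] = 0.35
    eff.loc["heart_rate", "nat"] = -0.3
    eff.loc["e_a", "sat"] = -0.45
    eff.loc["septal_ea", "sat"] = -0.45
    eff.loc["dbp", "sat"] = 0.4
    eff.loc["heart_rate", "sat"] = 0.3
    eff.loc["svr", "sat"] = -0.35
    eff.loc["co", "sat"] = 0.3
    return eff


@dataclass(frozen=True)
class CohortSpec:
    """Simulated adolescent cohort with a known standardized effect matrix.

    ``effects`` maps each outcome to standardized coefficients on the
    z-scored latent predictors {nat, sat, vat, age, sex}.  Compartment
    latents share the correlation structure ``compartment_corr``
    ((nat,sat), (nat,vat), (sat,vat) pairwise correlations).  Variables in
    ``skewed_vars`` are realized as shifted lognormals of their latent.
    """

    n: int = 82
    effects: pd.DataFrame | None = None  # defaults to default_effects()
    compartment_corr: tuple[float, float, float] = (0.55, 0.40, 0.60)
    noise_sd: Mapping[str, float] | None = None  # per-outcome override
    skewed_vars: tuple[str, ...] = ("sat", "vat")
    clinic_count: int = 3
    age_range: tuple[float, float] = (13.0, 18.0)
    female_fraction: float = 0.44
    seed: int = 0

    def resolved_effects(self) -> pd.DataFrame:
        eff = self.effects if self.effects is not None else default_effects()
        eff = eff.reindex(index=list(COHORT_OUTCOMES), columns=list(COHORT_PREDICTORS))
        return eff.fillna(0.0)

    def predictor_cov(self) -> np.ndarray:
        c_ns, c_nv, c_sv = self.compartment_corr
        cov = np.eye(5)
        cov[0, 1] = cov[1, 0] = c_ns
        cov[0, 2] = cov[2, 0] = c_nv
        cov[1, 2] = cov[2, 1] = c_sv
        return cov

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size n must be >= 10")
        if not 0 <= self.clinic_count <= self.n:
            raise ValueError("clinic_count must lie in [0, n]")
        eigs = np.linalg.eigvalsh(self.predictor_cov())
        if eigs.min() <= 1e-10:
            raise ValueError(
                "compartment correlation structure is not positive definite"
            )


def _shifted_lognormal(z: np.ndarray, shift: float, mu: float, sigma: float) -> np.ndarray:
    return shift + np.exp(mu + sigma * z)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort table; returns (table, true standardized effects).

    Outcomes are built on the z scale as effects @ z-predictors plus
    Gaussian noise scaled so each outcome has (approximately) unit latent
    variance, then mapped affinely onto physiological scales.  Affine
    mapping preserves standardized coefficients, so the recorded effect
    matrix is the recovery target for downstream association models.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    eff = spec.resolved_effects()

    cov3 = spec.predictor_cov()[:3, :3]
    chol = np.linalg.cholesky(cov3)
    z_comp = rng.standard_normal((n, 3)) @ chol.T  # nat, sat, vat latents

    age = rng.uniform(*spec.age_range, size=n)
    sex = (rng.uniform(size=n) >= spec.female_fraction).astype(int)  # 1 = male
    age_sd = (spec.age_range[1] - spec.age_range[0]) / np.sqrt(12.0)
    p_m = 1.0 - spec.female_fraction
    z_pred = np.column_stack(
        [
            z_comp,
            (age - np.mean(spec.age_range)) / age_sd,
            (sex - p_m) / np.sqrt(p_m * (1.0 - p_m)),
        ]
    )

    cov5 = spec.predictor_cov()
    noise_override = dict(spec.noise_sd or {})
    table: dict[str, np.ndarray] = {}
    for outcome in COHORT_OUTCOMES:
        beta = eff.loc[outcome].to_numpy()
        explained = float(beta @ cov5 @ beta)
        sd = noise_override.get(outcome, np.sqrt(max(1.0 - explained, 0.05)))
        y = z_pred @ beta + rng.normal(0.0, sd, size=n)
        loc, scale = _OUTCOME_SCALE[outcome]
        table[outcome] = np.maximum(loc + scale * y, 0.01 * loc)

    # compartments on natural scales; skewed ones as shifted lognormals
    z_nat, z_sat, z_vat = z_comp.T
    nat = 34.0 + 7.0 * z_nat if "nat" not in spec.skewed_vars else _shifted_lognormal(z_nat, 20.0, np.log(14.0), 0.45)
    sat = 18.0 + 8.0 * z_sat if "sat" not in spec.skewed_vars else _shifted_lognormal(z_sat, 2.0, np.log(13.0), 0.55)
    vat = 0.9 + 0.35 * z_vat if "vat" not in spec.skewed_vars else _shifted_lognormal(z_vat, 0.15, np.log(0.65), 0.60)
    nat = np.maximum(nat, 5.0)
    sat = np.maximum(sat, 0.5)
    vat = np.maximum(vat, 0.05)

    height = 152.0 + 2.2 * (age - 13.0) + 7.0 * sex + rng.normal(0.0, 5.0, size=n)
    # scaled so the bundled LMS reference splits a default cohort into
    # roughly even normal / overweight groups with a small out-of-range tail
    weight = 0.65 * (nat + 0.92 * (sat + vat)) + 30.0 + rng.normal(0.0, 2.0, size=n)
    waist = 48.0 + 1.3 * sat + 4.0 * vat + rng.normal(0.0, 2.5, size=n)

    frame = pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "height_cm": height,
            "weight_kg": weight,
            "waist_cm": waist,
            "nat": nat,
            "sat": sat,
            "vat": vat,
        }
    )
    for outcome in COHORT_OUTCOMES:
        frame[outcome] = table[outcome]

    # clinic recruits: flag the most adipose subjects, mirroring referral
    clinic = np.zeros(n, dtype=bool)
    if spec.clinic_count:
        order = np.argsort(sat + vat)[::-1]
        clinic[order[: spec.clinic_count]] = True
    frame["clinic_recruit"] = clinic

    return frame, eff
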