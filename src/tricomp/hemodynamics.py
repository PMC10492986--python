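"""Derived cardiovascular indices: QA-method pulse wave velocity, stroke
volume, ejection fraction, cardiac output, LV mass, total arterial
compliance, and systemic vascular resistance.

Pulse wave velocity uses the flow-area relation: in the reflection-free
part of early systole the aortic lumen is locally linear in flow, and the
ratio of the flow gradient to the area gradient equals the wave speed.
With Q in mL/s and A in mm^2 the ratio is already in m/s
(1 mL/s / 1 mm^2 = 1000 mm/s = 1 m/s), so no numeric conversion factor
appears beyond the unit bookkeeping documented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FlowAreaWaveform",
    "VentricularVolumes",
    "PressureSet",
    "HemodynamicSummary",
    "WindowConfig",
    "EstimationError",
    "early_systolic_window",
    "pwv_qa",
    "stroke_volume",
    "ejection_fraction",
    "cardiac_output",
    "lv_mass",
    "tac",
    "svr",
    "summarize",
]

LV_MYOCARDIAL_DENSITY_G_PER_ML = 1.05


class EstimationError(RuntimeError):
    """Raised when a waveform does not support the requested estimate."""


@dataclass(frozen=True)
class FlowAreaWaveform:
    """Sampled aortic flow Q (mL/s) and lumen area A (mm^2) over one cycle."""

    t_ms: np.ndarray
    q_ml_s: np.ndarray
    a_mm2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, float)
        q = np.asarray(self.q_ml_s, float)
        a = np.asarray(self.a_mm2, float)
        if not (t.size == q.size == a.size):
            raise ValueError("t, Q, A must have equal lengths")
        if t.size < 10:
            raise ValueError("waveform needs at least 10 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "q_ml_s", q)
        object.__setattr__(self, "a_mm2", a)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FlowAreaWaveform":
        return cls(
            frame["t_ms"].to_numpy(),
            frame["Q_ml_s"].to_numpy(),
            frame["A_mm2"].to_numpy(),
        )


@dataclass(frozen=True)
class VentricularVolumes:
    edv_ml: float
    esv_ml: float
    myocardial_volume_ml: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.esv_ml <= self.edv_ml:
            raise ValueError("require 0 <= ESV <= EDV")
        if self.myocardial_volume_ml < 0:
            raise ValueError("myocardial volume must be >= 0")


@dataclass(frozen=True)
class PressureSet:
    sbp: float
    dbp: float
    heart_rate: float
    mbp: float | None = None
    mbp_derived: bool = False

    def __post_init__(self) -> None:
        if self.dbp >= self.sbp:
            raise ValueError("require DBP < SBP")
        if self.mbp is None:
            # oscillometric MBP unavailable: fall back to DBP + PP/3
            object.__setattr__(self, "mbp", self.dbp + (self.sbp - self.dbp) / 3.0)
            object.__setattr__(self, "mbp_derived", True)
        elif not self.dbp <= self.mbp <= self.sbp:
            raise ValueError("MBP must lie between DBP and SBP")

    @property
    def pulse_pressure(self) -> float:
        return self.sbp - self.dbp


@dataclass(frozen=True)
class HemodynamicSummary:
    pwv_m_s: float
    sv_ml: float
    ef_percent: float
    co_l_min: float
    lv_mass_g: float
    mass_to_edv_g_ml: float
    tac_ml_mmhg: float
    svr_wu: float
    pulse_pressure_mmhg: float


@dataclass(frozen=True)
class WindowConfig:
    """Early-systolic window selection and slope-fit settings."""

    foot_fraction: float = 0.05  # upstroke foot: first sample above this x peak Q
    r2_min: float = 0.98  # joint linearity criterion for Q(t) and A(t)
    min_samples: int = 4
    max_systole_fraction: float = 0.40
    check_sign_runs: bool = True
    estimator: str = "huber"  # or "ols"
    huber_t: float = 1.345
    min_delta_a_mm2: float = 1e-9


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = float((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 1.0 if np.allclose(y, 0) else 0.0
    return float((x * y).sum() ** 2 / denom)


def _residual_runs_ok(x: np.ndarray, y: np.ndarray) -> bool:
    """Reject windows whose linear-fit residuals are grossly one-signed."""
    n = x.size
    if n < 8:
        return True
    slope, intercept = np.polyfit(x, y, 1)
    res = y - (slope * x + intercept)
    signs = np.sign(res)
    signs = signs[signs != 0]
    if signs.size < 4:
        return True
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    return runs >= max(2, signs.size // 3)


def early_systolic_window(
    wf: FlowAreaWaveform, config: WindowConfig = WindowConfig()
) -> tuple[int, int]:
    """Locate the initial linear segment of the systolic upstroke.

    Returns an inclusive-exclusive index range (start, stop).  The window
    starts at the flow-upstroke foot and expands while straight-line fits
    of both Q(t) and A(t) stay above the R^2 floor and the residuals do not
    become systematically one-signed, capped at a fraction of systole.
    """
    q = wf.q_ml_s
    peak = float(q.max())
    if peak <= 0:
        raise EstimationError("no systolic upstroke: max Q <= 0")
    foot_level = config.foot_fraction * peak
    above = np.flatnonzero(q >= foot_level)
    if above.size == 0:
        raise EstimationError("no samples above the upstroke foot level")
    foot = int(above[0])
    peak_idx = int(np.argmax(q))
    if peak_idx <= foot:
        raise EstimationError("flow peak precedes the detected foot")
    # systole: foot through the end of forward flow
    after_peak = np.flatnonzero(q[peak_idx:] < foot_level)
    sys_end = peak_idx + (int(after_peak[0]) if after_peak.size else q.size - peak_idx)
    max_len = max(config.min_samples, int(config.max_systole_fraction * (sys_end - foot)))
    max_stop = min(foot + max_len, wf.t_ms.size)

    if max_stop - foot < config.min_samples:
        raise EstimationError("systolic upstroke too short for the minimum window")

    # scan every candidate stop and keep the longest window that passes the
    # joint linearity criterion; under noise the shortest windows fail R^2
    # even inside the linear segment, so breaking at the first failure would
    # systematically pick noise-dominated 4-sample windows
    best_stop = None
    fallback_stop, fallback_r2 = foot + config.min_samples, -np.inf
    for stop in range(foot + config.min_samples, max_stop + 1):
        t = wf.t_ms[foot:stop]
        r2_joint = min(
            _r2(t, wf.q_ml_s[foot:stop]), _r2(t, wf.a_mm2[foot:stop])
        )
        if r2_joint > fallback_r2:
            fallback_stop, fallback_r2 = stop, r2_joint
        ok = r2_joint >= config.r2_min
        if ok and config.check_sign_runs:
            ok = _residual_runs_ok(t, wf.q_ml_s[foot:stop]) and _residual_runs_ok(
                t, wf.a_mm2[foot:stop]
            )
        if ok:
            best_stop = stop
    return foot, best_stop if best_stop is not None else fallback_stop


def _slope(t: np.ndarray, y: np.ndarray, config: WindowConfig) -> float:
    X = sm.add_constant(t)
    if config.estimator == "ols":
        return float(sm.OLS(y, X).fit().params[1])
    if config.estimator == "huber":
        model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=config.huber_t))
        return float(model.fit().params[1])
    raise ValueError(f"unknown estimator {config.estimator!r}")


def pwv_qa(
    wf: FlowAreaWaveform,
    window: tuple[int, int] | None = None,
    config: WindowConfig = WindowConfig(),
) -> float:
    """Pulse wave velocity (m/s) as the flow gradient over the area gradient.

    Slopes of Q(t) and A(t) are fit over the early-systolic window with a
    robust (Huber) or OLS estimator; their ratio, with Q in mL/s and A in
    mm^2, is the wave speed in m/s.
    """
    if window is None:
        window = early_systolic_window(wf, config)
    i, j = window
    if j - i < 2:
        raise EstimationError("window too short for slope estimation")
    t = wf.t_ms[i:j]
    a = wf.a_mm2[i:j]
    q = wf.q_ml_s[i:j]
    if float(np.ptp(a)) < config.min_delta_a_mm2:
        raise EstimationError("incompressible segment: |dA| below tolerance")
    slope_q = _slope(t, q, config)  # mL/s per ms
    slope_a = _slope(t, a, config)  # mm^2 per ms
    if abs(slope_a) < 1e-15:
        raise EstimationError("incompressible segment: area slope ~ 0")
    # (mL/s)/mm^2 = 1000 mm^3/s / mm^2 = 1000 mm/s = 1 m/s
    return slope_q / slope_a


# ---------------------------------------------------------------------------
# closed-form indices
# ---------------------------------------------------------------------------

def stroke_volume(v: VentricularVolumes) -> float:
    """SV = EDV - ESV, in mL."""
    return v.edv_ml - v.esv_ml


def ejection_fraction(v: VentricularVolumes) -> float:
    """EF = 100 * SV / EDV, in percent."""
    if v.edv_ml == 0:
        raise ValueError("EF undefined for EDV = 0")
    return 100.0 * stroke_volume(v) / v.edv_ml


def lv_mass(myocardial_volume_ml: float) -> float:
    """LV myocardial mass (g) from myocardial volume (mL) at density 1.05 g/mL."""
    if myocardial_volume_ml < 0:
        raise ValueError("myocardial volume must be >= 0")
    return LV_MYOCARDIAL_DENSITY_G_PER_ML * myocardial_volume_ml


def cardiac_output(sv_ml: float, heart_rate_bpm: float) -> float:
    """CO = SV x HR, converted mL/min -> L/min."""
    if sv_ml < 0 or heart_rate_bpm < 0:
        raise ValueError("SV and heart rate must be >= 0")
    return sv_ml * heart_rate_bpm / 1000.0


def tac(sv_ml: float, p: PressureSet) -> float:
    """Total arterial compliance = SV / pulse pressure, mL/mmHg."""
    if p.pulse_pressure <= 0:
        raise ValueError("pulse pressure must be positive")
    return sv_ml / p.pulse_pressure


def svr(p: PressureSet, co_l_min: float) -> float:
    """Systemic vascular resistance = MBP / CO, Wood units (mmHg.min/L)."""
    if co_l_min <= 0:
        raise ValueError("cardiac output must be positive")
    return p.mbp / co_l_min


def summarize(
    wf: FlowAreaWaveform | None,
    v: VentricularVolumes,
    p: PressureSet,
    config: WindowConfig = WindowConfig(),
) -> HemodynamicSummary:
    """Assemble the full derived-index summary for one subject."""
    sv = stroke_volume(v)
    co = cardiac_output(sv, p.heart_rate)
    mass = lv_mass(v.myocardial_volume_ml)
    return HemodynamicSummary(
        pwv_m_s=pwv_qa(wf, config=config) if wf is not None else float("nan"),
        sv_ml=sv,
        ef_percent=ejection_fraction(v),
        co_l_min=co,
        lv_mass_g=mass,
        mass_to_edv_g_ml=mass / v.edv_ml if v.edv_ml else float("nan"),
        tac_ml_mmhg=tac(sv, p),
        svr_wu=svr(p, co),
        pulse_pressure_mmhg=p.pulse_pressure,
    )
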