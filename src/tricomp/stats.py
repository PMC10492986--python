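"""Statistical core: zero-skew log transform, OLS residualization, the
orthogonalized three-compartment predictor set, and standardized
age/sex-adjusted association tables.

The three-compartment construction regresses SAT on NAT (residual = rSAT)
and VAT on NAT and rSAT (residual = rVAT), following the lipid-spillover
ordering, so NAT, rSAT, and rVAT are pairwise uncorrelated and their
standardized coefficients in a joint model can be read independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ResidualizedCompartments",
    "AssociationModel",
    "lnskew0",
    "residualize",
    "build_three_compartments",
    "standardized_association",
    "association_grid",
    "sensitivity_exclude",
    "significance_mark",
    "DEFAULT_OUTCOMES",
    "MODEL_SPECS",
]

P_SIGNIFICANT = 0.01
P_TREND = 0.05
SKEW_TRIGGER = 0.5

DEFAULT_OUTCOMES = (
    "sbp", "dbp", "mbp", "pulse_pressure", "svr", "co", "sv", "heart_rate",
    "lvedv", "lvef", "lv_mass", "mass_to_edv", "e_a", "septal_ea",
    "lateral_ea", "pwv_aao", "pwv_dao", "tac",
)

MODEL_SPECS = ("anthro", "bmi-adj-nat", "three-comp")


# ---------------------------------------------------------------------------
# zero-skew log transform
# ---------------------------------------------------------------------------

def _skew(y: np.ndarray) -> float:
    return float(sps.skew(y, bias=True))


def lnskew0(x: Sequence[float]) -> tuple[float, np.ndarray]:
    """Shifted log transform with zero sample skewness.

    For positively skewed ``x`` finds k < min(x) with skew(ln(x - k)) = 0
    and returns (k, ln(x - k)); for negatively skewed input the mirrored
    form ln(k - x) with k > max(x) is used and k is returned negated to
    mark the reflection.  Root-finding targets |skew| < 1e-8.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("lnskew0 requires at least 8 observations")
    if np.ptp(x) == 0:
        raise ValueError("lnskew0 undefined for a constant sample")

    direction = 1.0 if _skew(x) >= 0 else -1.0
    w = direction * x  # work on a positively skewed copy

    lo_edge = float(w.min())
    span = float(np.ptp(w))

    def g(k: float) -> float:
        return _skew(np.log(w - k))

    # as k -> min(w)^- the log blows up the left tail (skew -> -inf);
    # as k -> -inf the transform becomes affine (skew -> skew(w) > 0)
    hi = lo_edge - 1e-9 * max(span, abs(lo_edge), 1.0)
    lo = lo_edge - span
    tries = 0
    while g(lo) <= 0 and tries < 200:
        lo = lo_edge - (lo_edge - lo) * 2.0
        tries += 1
    if g(lo) <= 0 or g(hi) >= 0:
        raise ValueError(
            f"no zero-skew shift found in bracket [{lo:.6g}, {hi:.6g}]"
        )
    k = float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=500))
    y = np.log(w - k)
    if abs(_skew(y)) > 1e-8:
        raise ValueError("root-finding failed to reach |skew| < 1e-8")
    return direction * k, y


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def residualize(y: Sequence[float], X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Residuals of an intercept-included OLS fit of y on X.

    The result is orthogonal to the constant and every column of X.
    Raises on rank deficiency, naming the collinear columns when X is a
    DataFrame.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = [f"x{i}" for i in range(Xa.shape[1])]
    if Xa.shape[0] != y.size:
        raise ValueError("y and X must have equal row counts")
    if y.size <= Xa.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    design = np.column_stack([np.ones(y.size), Xa])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by rank increments
        bad = []
        cols = [np.ones(y.size)]
        for j in range(Xa.shape[1]):
            trial = np.column_stack(cols + [Xa[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(names[j])
            else:
                cols.append(Xa[:, j])
        raise ValueError(f"rank-deficient covariate set; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


@dataclass(frozen=True)
class ResidualizedCompartments:
    nat: np.ndarray
    rsat: np.ndarray
    rvat: np.ndarray
    flags: tuple[str, ...] = ()

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nat": self.nat, "rsat": self.rsat, "rvat": self.rvat})

    def max_abs_correlation(self) -> float:
        f = self.frame()
        c = f.corr().to_numpy()
        return float(np.max(np.abs(c[~np.eye(3, dtype=bool)])))


def build_three_compartments(
    nat: Sequence[float],
    sat: Sequence[float],
    vat: Sequence[float],
    extra_covariates: np.ndarray | None = None,
) -> ResidualizedCompartments:
    """Sequentially residualize SAT and VAT against NAT (spillover order).

    rSAT = residual of SAT on NAT; rVAT = residual of VAT on NAT and rSAT.
    The three outputs are pairwise uncorrelated by construction.  By default
    only tissue compartments enter the residualizing regressions;
    ``extra_covariates`` (e.g. age/sex columns) can be added for
    sensitivity variants.
    """
    nat = np.asarray(nat, float)
    sat = np.asarray(sat, float)
    vat = np.asarray(vat, float)
    if not (nat.size == sat.size == vat.size):
        raise ValueError("compartment vectors must have equal lengths")
    if nat.size < 10:
        raise ValueError("need at least 10 subjects")
    extra = (
        np.empty((nat.size, 0))
        if extra_covariates is None
        else np.atleast_2d(np.asarray(extra_covariates, float).T).T
    )
    rsat = residualize(sat, np.column_stack([nat, extra]))
    flags: list[str] = []
    if float(np.std(rsat)) < 1e-12 * max(float(np.std(sat)), 1.0):
        flags.append("degenerate_rsat")
        rvat = residualize(vat, np.column_stack([nat, extra]))
    else:
        rvat = residualize(vat, np.column_stack([nat, rsat, extra]))
    if float(np.std(rvat)) < 1e-12 * max(float(np.std(vat)), 1.0):
        flags.append("degenerate_rvat")
    return ResidualizedCompartments(nat=nat, rsat=rsat, rvat=rvat, flags=tuple(flags))


# ---------------------------------------------------------------------------
# standardized association models
# ---------------------------------------------------------------------------

def significance_mark(p: float) -> str:
    """'significant' below 0.01, 'trend' in [0.01, 0.05), else 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < P_SIGNIFICANT:
        return "significant"
    if p < P_TREND:
        return "trend"
    return "ns"


def _is_binary(v: np.ndarray) -> bool:
    u = np.unique(v[~np.isnan(v)])
    return u.size <= 2


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable cannot be z-scored")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class AssociationModel:
    """Configuration for standardized, covariate-adjusted linear models."""

    covariates: tuple[str, ...] = ("age", "sex")
    transform_skewed: bool = True
    skew_trigger: float = SKEW_TRIGGER
    transform_overrides: Mapping[str, bool] = field(default_factory=dict)


def _maybe_lnskew0(name: str, v: np.ndarray, model: AssociationModel) -> tuple[np.ndarray, bool]:
    override = model.transform_overrides.get(name)
    apply = override if override is not None else (
        model.transform_skewed
        and np.all(v > 0)
        and abs(_skew(v)) > model.skew_trigger
    )
    if not apply:
        return v, False
    try:
        _, y = lnskew0(v)
        return y, True
    except ValueError:
        return v, False


def standardized_association(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    model: AssociationModel = AssociationModel(),
    model_id: str = "custom",
) -> pd.DataFrame:
    """Joint linear model of a z-scored outcome on z-scored predictors.

    The outcome and every non-binary predictor are standardized after the
    optional zero-skew log transform, covariates (binary ones centered
    only) are added, and the fitted coefficient of each predictor is
    reported as the standardized association with a two-sided t-test p
    value.  Rows with missing values are dropped listwise.
    """
    cols = [outcome, *predictors, *model.covariates]
    sub = data[cols].dropna()
    n = len(sub)
    k = len(predictors) + len(model.covariates)
    if n <= k + 2:
        raise ValueError("too few complete cases for the requested model")

    y_raw = sub[outcome].to_numpy(float)
    y, y_transformed = _maybe_lnskew0(outcome, y_raw, model)
    y = _zscore(y)

    design_cols: list[np.ndarray] = []
    for name in (*predictors, *model.covariates):
        v = sub[name].to_numpy(float)
        if _is_binary(v):
            design_cols.append(v - v.mean())
        else:
            design_cols.append(_zscore(v))
    X = np.column_stack([np.ones(n), *design_cols])

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)

    rows = []
    for j, name in enumerate(predictors, start=1):
        rows.append(
            {
                "outcome": outcome,
                "predictor": name,
                "model": model_id,
                "r": float(beta[j]),
                "p": float(pvals[j]),
                "n": n,
                "significant": significance_mark(float(pvals[j])),
                "transformed": bool(y_transformed),
            }
        )
    return pd.DataFrame(rows)


def _with_three_compartments(cohort: pd.DataFrame) -> pd.DataFrame:
    rc = build_three_compartments(
        cohort["nat"].to_numpy(float),
        cohort["sat"].to_numpy(float),
        cohort["vat"].to_numpy(float),
    )
    out = cohort.copy()
    out["rsat"] = rc.rsat
    out["rvat"] = rc.rvat
    return out


def association_grid(
    cohort: pd.DataFrame,
    model_spec: str,
    outcomes: Iterable[str] = DEFAULT_OUTCOMES,
    model: AssociationModel = AssociationModel(),
) -> pd.DataFrame:
    """One standardized-association row per outcome x predictor for a model.

    model_spec:
      ``anthro``       three single-anthropometric models per outcome
                       (bmi_z, waist_z, waist_height_z, each age/sex-adjusted)
      ``bmi-adj-nat``  BMI z-score residualized on NAT as the sole predictor
      ``three-comp``   NAT, rSAT, rVAT entered jointly with age and sex
    """
    if model_spec not in MODEL_SPECS:
        raise ValueError(f"unknown model_spec {model_spec!r}; choose from {MODEL_SPECS}")
    outcomes = list(outcomes)
    frames: list[pd.DataFrame] = []

    if model_spec == "anthro":
        for outcome in outcomes:
            for predictor in ("bmi_z", "waist_z", "waist_height_z"):
                frames.append(
                    standardized_association(
                        cohort, outcome, [predictor], model, model_id="anthro"
                    )
                )
    elif model_spec == "bmi-adj-nat":
        data = cohort.copy()
        data["bmi_z_adj_nat"] = residualize(
            data["bmi_z"].to_numpy(float), data[["nat"]]
        )
        for outcome in outcomes:
            frames.append(
                standardized_association(
                    data, outcome, ["bmi_z_adj_nat"], model, model_id="bmi-adj-nat"
                )
            )
    else:  # three-comp
        data = _with_three_compartments(cohort)
        for outcome in outcomes:
            frames.append(
                standardized_association(
                    data, outcome, ["nat", "rsat", "rvat"], model, model_id="three-comp"
                )
            )
    return pd.concat(frames, ignore_index=True)


def sensitivity_exclude(
    cohort: pd.DataFrame,
    model_spec: str,
    flag: str = "clinic_recruit",
    outcomes: Iterable[str] = DEFAULT_OUTCOMES,
    model: AssociationModel = AssociationModel(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Re-run an association grid excluding flagged subjects.

    Returns (full table, excluded-run table, comparison of coefficients).
    """
    if flag not in cohort.columns:
        raise ValueError(f"flag column {flag!r} not present")
    kept = cohort[~cohort[flag].astype(bool)]
    if kept.empty:
        raise ValueError("excluding flagged subjects empties the analysis set")
    full = association_grid(cohort, model_spec, outcomes, model)
    excl = association_grid(kept, model_spec, outcomes, model)
    merged = full.merge(
        excl, on=["outcome", "predictor", "model"], suffixes=("_full", "_excl")
    )
    merged["r_delta"] = merged["r_excl"] - merged["r_full"]
    comparison = merged[
        ["outcome", "predictor", "model", "r_full", "r_excl", "r_delta", "p_full", "p_excl"]
    ]
    return full, excl, comparison
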