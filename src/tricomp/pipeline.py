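"""End-to-end pipeline: simulate or load a cohort, derive anthropometric
columns, summarize groups, and produce all association tables with a
provenance block.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tricomp import __version__, anthropometry, stats
from tricomp.synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize_groups"]

_GROUP_VARIABLES = (
    "age", "height_cm", "weight_kg", "bsa", "bmi", "bmi_z", "waist_cm",
    "waist_z", "waist_height_z", "nat", "sat", "vat",
    *stats.DEFAULT_OUTCOMES,
)


@dataclass(frozen=True)
class RunConfig:
    """Flat, auditable configuration for one pipeline run."""

    cohort_csv: Path | None = None  # None -> simulate
    n: int = 82
    clinic_count: int = 3
    seed: int = 0
    models: tuple[str, ...] = stats.MODEL_SPECS
    exclude_clinic: bool = True
    out_dir: Path | None = None

    @classmethod
    def from_file(cls, path: Path) -> "RunConfig":
        """Parse a flat key=value config file (comments with #)."""
        values: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        kwargs: dict = {}
        if "cohort_csv" in values and values["cohort_csv"]:
            kwargs["cohort_csv"] = Path(values["cohort_csv"])
        for key in ("n", "clinic_count", "seed"):
            if key in values:
                kwargs[key] = int(values[key])
        if "models" in values:
            kwargs["models"] = tuple(m.strip() for m in values["models"].split(",") if m.strip())
        if "exclude_clinic" in values:
            kwargs["exclude_clinic"] = values["exclude_clinic"].lower() in ("1", "true", "yes")
        if "out_dir" in values and values["out_dir"]:
            kwargs["out_dir"] = Path(values["out_dir"])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(self.cohort_csv)
        unknown = set(self.models) - set(stats.MODEL_SPECS)
        if unknown:
            raise ValueError(
                f"unknown model spec(s) {sorted(unknown)}; valid: {stats.MODEL_SPECS}"
            )
        if self.cohort_csv is None and self.n < 10:
            raise ValueError("simulated cohort needs n >= 10")

    def content_hash(self) -> str:
        text = "|".join(
            f"{k}={getattr(self, k)}"
            for k in ("cohort_csv", "n", "clinic_count", "seed", "models", "exclude_clinic")
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    cohort: pd.DataFrame
    group_table: pd.DataFrame
    association_tables: dict[str, pd.DataFrame]
    sensitivity_tables: dict[str, pd.DataFrame]
    exclusions: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def body_text(self) -> str:
        """Deterministic report body (no timestamps)."""
        parts = [
            "tricomp run report",
            f"config_hash: {self.provenance.get('config_hash')}",
            f"seed: {self.provenance.get('seed')}",
            f"version: {self.provenance.get('version')}",
            f"n: {len(self.cohort)}",
            "",
            "== group comparison (median [IQR]) ==",
            self.group_table.to_csv(index=False),
            "",
        ]
        for name, table in sorted(self.association_tables.items()):
            parts.append(f"== associations: {name} ==")
            parts.append(table.to_csv(index=False))
        for name, table in sorted(self.sensitivity_tables.items()):
            parts.append(f"== sensitivity (clinic excluded): {name} ==")
            parts.append(table.to_csv(index=False))
        parts.append("== exclusions ==")
        parts.append(self.exclusions.to_csv(index=False))
        return "\n".join(parts)


def _fmt(v: float, decimals: int) -> str:
    return f"{v:.{decimals}f}"


def summarize_groups(cohort: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Median (IQR) per weight-status group plus count (percent) rows.

    Single-subject groups get a flag since the IQR degenerates to the
    point value; empty groups are omitted with a flag row.
    """
    if "weight_status" not in cohort.columns:
        raise ValueError("cohort lacks a weight_status column")
    groups = ["normal", "overweight/obese"]
    n_total = len(cohort)
    rows: list[dict] = []
    counts = {}
    for g in groups:
        sub = cohort[cohort["weight_status"] == g]
        counts[g] = len(sub)
    row = {"variable": "No. (%)"}
    for g in groups:
        pct = round(100.0 * counts[g] / n_total) if n_total else 0
        row[g] = f"{counts[g]} ({pct:.0f})"
    rows.append(row)
    for g in groups:
        if counts[g] == 0:
            rows.append({"variable": f"flag:empty_group:{g}", g: ""})
        elif counts[g] == 1:
            rows.append({"variable": f"flag:single_subject_group:{g}", g: ""})
    for var in _GROUP_VARIABLES:
        if var not in cohort.columns:
            continue
        row = {"variable": var}
        for g in groups:
            sub = cohort.loc[cohort["weight_status"] == g, var].dropna()
            if sub.empty:
                row[g] = ""
                continue
            med = float(sub.median())
            q1, q3 = (float(sub.quantile(q)) for q in (0.25, 0.75))
            row[g] = f"{_fmt(med, decimals)} ({_fmt(q1, decimals)} to {_fmt(q3, decimals)})"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the cohort-level pipeline per the config; deterministic."""
    config.validate()

    if config.cohort_csv is not None:
        cohort = pd.read_csv(config.cohort_csv)
    else:
        cohort, _ = generate_cohort(
            CohortSpec(n=config.n, clinic_count=config.clinic_count, seed=config.seed)
        )
    if "bmi_z" not in cohort.columns:
        cohort = anthropometry.augment_cohort(cohort)

    # out-of-range subjects leave two-group comparisons but stay in models
    excluded = cohort[cohort["weight_status"] == "underweight/out-of-range"]
    exclusions = pd.DataFrame(
        {
            "id": excluded.get("id", pd.Series(dtype=str)),
            "reason": ["bmi_z <= -2 (out of range for group comparison)"] * len(excluded),
        }
    )

    group_table = summarize_groups(cohort)

    association_tables: dict[str, pd.DataFrame] = {}
    sensitivity_tables: dict[str, pd.DataFrame] = {}
    for spec_name in config.models:
        association_tables[spec_name] = stats.association_grid(cohort, spec_name)
        if config.exclude_clinic and "clinic_recruit" in cohort.columns:
            _, excl, comparison = stats.sensitivity_exclude(cohort, spec_name)
            sensitivity_tables[spec_name] = comparison

    report = RunReport(
        cohort=cohort,
        group_table=group_table,
        association_tables=association_tables,
        sensitivity_tables=sensitivity_tables,
        exclusions=exclusions,
        provenance={
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv", index=False)
        group_table.to_csv(out / "group_table.csv", index=False)
        for name, table in association_tables.items():
            table.to_csv(out / f"associations_{name.replace('-', '_')}.csv", index=False)
        for name, table in sensitivity_tables.items():
            table.to_csv(out / f"sensitivity_{name.replace('-', '_')}.csv", index=False)
        (out / "report.txt").write_text(report.body_text())
    return report
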