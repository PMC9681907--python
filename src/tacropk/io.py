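"""Reading and writing datasets, configurations and result tables.

Datasets are comma-delimited text with a header, one row per trough
observation.  A *dialect* maps the canonical field names used internally
to the column names in the file, so files produced by other TDM systems
can be ingested without rewriting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AnalysisConfig,
    ObservationRow,
    SubjectRecord,
    frame_to_subjects,
    subjects_to_frame,
)
from .diagnostics import BootstrapResult, NpdeSummary, PredErrorSummary, VpcSummary
from .dosing import DoseTable
from .estimation import FitResult

__all__ = [
    "DatasetDialect",
    "read_dataset",
    "write_dataset",
    "write_results",
    "load_config",
    "RowError",
]

_CANONICAL = [f.name for f in dataclasses.fields(ObservationRow)] + [
    f.name for f in dataclasses.fields(SubjectRecord) if f.name != "rows"
]


@dataclass
class DatasetDialect:
    """Column mapping: canonical field name -> column name in the file."""

    columns: dict[str, str] = field(default_factory=dict)
    sep: str = ","

    def file_column(self, name: str) -> str:
        return self.columns.get(name, name)


@dataclass(frozen=True)
class RowError:
    subject_id: str
    line: int
    field: str
    value: str
    message: str


_REQUIRED = ("subject_id", "pod", "daily_dose", "c0")
_NUMERIC = [
    f.name
    for f in dataclasses.fields(ObservationRow)
    if f.name not in ("taf", "wuzhi", "ccb", "ppi", "mmf", "at_steady_state")
] + ["age", "weight", "height", "ffm", "graft_weight"]
_GENOTYPE = [
    f.name for f in dataclasses.fields(SubjectRecord) if f.name.startswith("genotype_")
]


def read_dataset(
    path: str | Path,
    dialect: DatasetDialect | None = None,
) -> tuple[list[SubjectRecord], list[RowError]]:
    """Load an analysis dataset.

    Rows failing numeric validation are reported (subject id, line,
    offending field) and skipped -- never silently dropped.  A missing
    required column raises immediately.
    """
    dialect = dialect or DatasetDialect()
    frame = pd.read_csv(path, sep=dialect.sep, dtype=str)
    rename = {dialect.file_column(k): k for k in _CANONICAL}
    frame = frame.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset at {path} is missing required columns: {missing}")

    errors: list[RowError] = []
    keep = np.ones(len(frame), dtype=bool)
    for col in _NUMERIC:
        if col not in frame.columns:
            continue
        vals = pd.to_numeric(frame[col], errors="coerce")
        if col in ("pod", "daily_dose", "c0"):
            bad = vals.isna()  # required per row: missing or non-numeric
        else:
            bad = vals.isna() & frame[col].notna()  # garbled text; blanks use LOCF
        for i in np.where(bad)[0]:
            errors.append(
                RowError(
                    subject_id=str(frame["subject_id"].iloc[i]),
                    line=int(i) + 2,  # header is line 1
                    field=col,
                    value=str(frame[col].iloc[i]),
                    message="non-numeric or missing value",
                )
            )
        keep &= ~bad.to_numpy()
        frame[col] = vals
    frame = frame.loc[keep].copy()

    # fill optional columns with defaults; carry within-subject LOCF for labs
    defaults = {
        f.name: f.default
        for f in dataclasses.fields(ObservationRow)
        if f.default is not dataclasses.MISSING
    }
    defaults.update(
        {
            f.name: f.default
            for f in dataclasses.fields(SubjectRecord)
            if f.default is not dataclasses.MISSING and f.name != "rows"
        }
    )
    for col, default in defaults.items():
        if col not in frame.columns:
            frame[col] = default
    if "at_steady_state" not in frame.columns:
        frame["at_steady_state"] = 1
    frame["at_steady_state"] = (
        pd.to_numeric(frame["at_steady_state"], errors="coerce").fillna(1).astype(int)
    )
    for col in ("taf", "wuzhi", "ccb", "ppi", "mmf"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce").fillna(0).astype(int)
    for col in _GENOTYPE:
        frame[col] = pd.to_numeric(frame[col], errors="coerce").fillna(0).astype(int)
    if "sex" in frame.columns:
        frame["sex"] = frame["sex"].fillna("male")
    lab_cols = [c for c in ("hct", "ast", "alt", "tbil", "alb", "scr", "clcr") if c in frame.columns]
    frame[lab_cols] = frame.groupby("subject_id")[lab_cols].ffill()
    for col in lab_cols:
        frame[col] = frame[col].fillna(defaults[col])
    return frame_to_subjects(frame), errors


def write_dataset(subjects: list[SubjectRecord], path: str | Path) -> None:
    frame = subjects_to_frame(subjects)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# results


def _fit_tables(fit: FitResult) -> tuple[pd.DataFrame, dict]:
    table = pd.DataFrame(fit.summary_rows())
    summary = {
        "ofv": fit.ofv,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "estimates": fit.estimates,
        "rse_percent": fit.rse_percent,
        "eta_shrinkage_percent": fit.eta_shrinkage,
        "eps_shrinkage_percent": fit.eps_shrinkage,
        "seed": fit.seed,
    }
    return table, summary


def write_results(obj, path: str | Path) -> list[Path]:
    """Write a result object as a delimited table plus a JSON summary.

    Accepts FitResult, BootstrapResult, VpcSummary, NpdeSummary,
    PredErrorSummary and DoseTable; returns the written paths.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump_json(payload: dict, suffix: str = ".json") -> None:
        p = path.with_suffix(suffix)
        p.write_text(json.dumps(payload, indent=2, default=_json_default))
        written.append(p)

    if isinstance(obj, FitResult):
        table, summary = _fit_tables(obj)
        p = path.with_suffix(".csv")
        table.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        dump_json(summary)
    elif isinstance(obj, BootstrapResult):
        rows = [
            {
                "parameter": k,
                "median": obj.medians[k],
                "ci95_lo": obj.ci_lo[k],
                "ci95_hi": obj.ci_hi[k],
                "bias_percent": obj.bias_percent[k],
            }
            for k in obj.medians
        ]
        p = path.with_suffix(".csv")
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        dump_json(
            {
                "n_requested": obj.n_requested,
                "n_converged": obj.n_converged,
                "convergence_rate": obj.convergence_rate,
            }
        )
    elif isinstance(obj, VpcSummary):
        rows = []
        for b in range(len(obj.bin_mid)):
            for j, pct in enumerate(obj.percentiles):
                rows.append(
                    {
                        "bin_mid_pod": obj.bin_mid[b],
                        "percentile": pct,
                        "observed": obj.obs_percentiles[b, j],
                        "sim_ci_lo": obj.sim_ci[b, j, 0],
                        "sim_ci_hi": obj.sim_ci[b, j, 1],
                    }
                )
        p = path.with_suffix(".csv")
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        dump_json({"coverage": obj.coverage()})
    elif isinstance(obj, NpdeSummary):
        dump_json(
            {
                "p_mean": obj.p_mean,
                "p_variance": obj.p_variance,
                "p_normality": obj.p_normality,
                "p_global": obj.p_global,
                "n": int(obj.npde.size),
            }
        )
        p = path.with_suffix(".csv")
        pd.DataFrame({"npde": obj.npde}).to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    elif isinstance(obj, PredErrorSummary):
        dump_json(dataclasses.asdict(obj))
    elif isinstance(obj, DoseTable):
        rows = []
        for c in obj.cells:
            s = c.scenario
            rows.append(
                {
                    "cyp3a5": "*1 carrier" if s.cyp3a5_carrier else "*3/*3",
                    "taf": s.taf,
                    "hct_band": f"{s.hct_band[0]:g}-{s.hct_band[1]:g}",
                    "tbil_band": f"{s.tbil_band[0]:g}-{s.tbil_band[1]:g}",
                    "dose_lo_mg": c.dose_lo,
                    "dose_hi_mg": c.dose_hi,
                    "median_dose_mg": c.median_dose,
                    "fraction_feasible": c.fraction_feasible,
                }
            )
        p = path.with_suffix(".csv")
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    else:
        raise TypeError(f"don't know how to write {type(obj).__name__}")
    return written


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def load_config(path: str | Path) -> AnalysisConfig:
    """Load run settings from a YAML mapping (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "target_window" in raw:
        raw["target_window"] = tuple(raw["target_window"])
    return AnalysisConfig(**raw)
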