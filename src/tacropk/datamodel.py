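"""Core dataset types for trough-based tacrolimus TDM analysis.

The analysis dataset is a steady-state representation: one row per trough
observation, carrying the concurrent total daily dose and the covariates
measured on that day.  There are no per-dose event rows -- every retained
trough was drawn after at least three repeated doses at a constant rate, so
(daily dose, trough, covariates) fully determines the likelihood
contribution under both structural models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObservationRow",
    "SubjectRecord",
    "AnalysisConfig",
    "ValidationFlag",
    "ValidationReport",
    "validate_dataset",
    "apply_exclusions",
    "FlatData",
    "subjects_to_frame",
    "frame_to_subjects",
]


@dataclass
class ObservationRow:
    """One trough occasion: postoperative day, dose, trough and covariates.

    Units follow routine clinical reporting: dose in mg/day, trough in
    ng/ml whole blood, hematocrit in percent, bilirubin in umol/L,
    transaminases in U/L, albumin in g/L, creatinine in umol/L.
    """

    pod: float
    daily_dose: float
    c0: float
    hct: float = 31.3
    ast: float = 45.0
    alt: float = 69.0
    tbil: float = 58.25
    alb: float = 37.0
    scr: float = 57.0
    clcr: float = 124.6
    taf: int = 0
    steroid_dose: float = 0.0
    wuzhi: int = 0
    ccb: int = 0
    ppi: int = 0
    mmf: int = 0
    at_steady_state: bool = True


@dataclass
class SubjectRecord:
    """A patient: demographics, genotypes and the ordered trough rows.

    Genotype fields code the number of variant alleles (for CYP3A5, the
    number of functional *1 alleles) as 0, 1 or 2, for the recipient and
    the donor liver separately.
    """

    subject_id: str
    sex: str = "male"  # {male, female}
    age: float = 51.0
    weight: float = 64.0
    height: float = 1.70
    ffm: float = 51.5
    graft_weight: float = 1300.0
    genotype_cyp3a5_recipient: int = 0
    genotype_cyp3a5_donor: int = 0
    genotype_cyp3a4_1g_recipient: int = 0
    genotype_cyp3a4_1g_donor: int = 0
    genotype_sumo4_recipient: int = 0
    genotype_sumo4_donor: int = 0
    genotype_nr112_recipient: int = 0
    genotype_nr112_donor: int = 0
    rows: list[ObservationRow] = field(default_factory=list)

    def sorted(self) -> "SubjectRecord":
        return replace(self, rows=sorted(self.rows, key=lambda r: r.pod))


@dataclass
class AnalysisConfig:
    """Run-level settings shared by the pipeline stages."""

    model_id: str = "MM"  # {MM, THEORY}
    seed: int = 12345
    loq: float = 2.0  # lower limit of quantification, ng/ml
    exclude_below_loq: bool = True
    n_bootstrap: int = 1000
    n_vpc_sim: int = 1000
    n_npde_sim: int = 2000
    n_dose_sim: int = 200
    dose_grid: float = 0.25  # mg
    target_window: tuple[float, float] = (8.0, 12.0)  # ng/ml
    time_factor_enabled: bool = True
    hct_units: str = "fraction"  # interpretation inside the partition model
    outer_maxiter: int = 400

    def __post_init__(self) -> None:
        if self.dose_grid <= 0:
            raise ValueError("dose grid step must be positive")
        lo, hi = self.target_window
        if not lo < hi:
            raise ValueError("target window lower bound must be below upper")
        for name in ("n_bootstrap", "n_vpc_sim", "n_npde_sim", "n_dose_sim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationFlag:
    subject_id: str
    pod: float | None
    code: str
    message: str


@dataclass
class ValidationReport:
    flags: list[ValidationFlag] = field(default_factory=list)

    @property
    def n_flags(self) -> int:
        return len(self.flags)

    def by_code(self, code: str) -> list[ValidationFlag]:
        return [f for f in self.flags if f.code == code]

    def __bool__(self) -> bool:  # truthy when something was flagged
        return bool(self.flags)


_PLAUSIBLE = {
    "hct": (5.0, 70.0),
    "ast": (1.0, 5000.0),
    "alt": (1.0, 5000.0),
    "tbil": (0.5, 1000.0),
    "alb": (10.0, 60.0),
    "scr": (5.0, 1000.0),
}


def validate_dataset(
    subjects: Sequence[SubjectRecord],
    loq: float = 2.0,
) -> ValidationReport:
    """Report-only screen of an analysis dataset.

    Flags troughs below the assay quantification limit, rows sampled off
    steady state, nonpositive doses/troughs and covariates outside broad
    physiologic plausibility ranges.  Never mutates or drops anything;
    exclusion is a separate explicit step (:func:`apply_exclusions`).
    """
    report = ValidationReport()
    for subj in subjects:
        if subj.age < 18:
            report.flags.append(
                ValidationFlag(subj.subject_id, None, "age", "adult cohort: age < 18")
            )
        for r in subj.rows:
            sid, pod = subj.subject_id, r.pod
            if not r.c0 > 0:
                report.flags.append(ValidationFlag(sid, pod, "nonpositive_c0", f"c0={r.c0}"))
            elif r.c0 < loq:
                report.flags.append(
                    ValidationFlag(sid, pod, "below_loq", f"c0={r.c0} < LOQ {loq}")
                )
            if not r.daily_dose > 0:
                report.flags.append(
                    ValidationFlag(sid, pod, "nonpositive_dose", f"daily_dose={r.daily_dose}")
                )
            if not r.at_steady_state:
                report.flags.append(
                    ValidationFlag(sid, pod, "not_steady_state", "fewer than 3 constant doses")
                )
            for name, (lo, hi) in _PLAUSIBLE.items():
                v = getattr(r, name)
                if not lo <= v <= hi:
                    report.flags.append(
                        ValidationFlag(sid, pod, "implausible_covariate", f"{name}={v}")
                    )
    return report


def apply_exclusions(
    subjects: Sequence[SubjectRecord],
    report: ValidationReport,
    codes: Iterable[str] = ("below_loq", "nonpositive_c0", "nonpositive_dose", "not_steady_state"),
) -> list[SubjectRecord]:
    """Drop rows carrying any of the given flag codes; keep everyone else."""
    codes = set(codes)
    flagged = {
        (f.subject_id, f.pod) for f in report.flags if f.code in codes and f.pod is not None
    }
    out: list[SubjectRecord] = []
    for subj in subjects:
        rows = [r for r in subj.rows if (subj.subject_id, r.pod) not in flagged]
        if rows:
            out.append(replace(subj, rows=rows))
    return out


# ---------------------------------------------------------------------------
# flat numeric view used by estimation / diagnostics / simulation

_ROW_COLS = [f.name for f in fields(ObservationRow)]
_SUBJ_COLS = [f.name for f in fields(SubjectRecord) if f.name != "rows"]


class FlatData:
    """Column-oriented view of a dataset, grouped by subject.

    ``columns`` maps lowercase covariate names to per-observation arrays.
    Derived columns: ``cyp3a5_carrier`` is 1 when the recipient carries at
    least one functional CYP3A5*1 allele, ``sex_female`` is a 0/1 flag.
    """

    def __init__(self, subjects: Sequence[SubjectRecord]):
        subjects = [s.sorted() for s in subjects]
        self.subject_ids: list[str] = [s.subject_id for s in subjects]
        counts = np.array([len(s.rows) for s in subjects], dtype=int)
        if np.any(counts == 0):
            raise ValueError("every subject must carry at least one observation")
        self.n_subjects = len(subjects)
        self.n_obs = int(counts.sum())
        self.counts = counts
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.subject_index = np.repeat(np.arange(self.n_subjects), counts)

        cols: dict[str, np.ndarray] = {}
        for name in _ROW_COLS:
            vals = [getattr(r, name) for s in subjects for r in s.rows]
            cols[name] = np.asarray(vals, dtype=float)
        for name in _SUBJ_COLS:
            if name in ("subject_id", "sex"):
                continue
            per_subj = np.asarray([getattr(s, name) for s in subjects], dtype=float)
            cols[name] = per_subj[self.subject_index]
        cols["sex_female"] = np.asarray(
            [1.0 if s.sex == "female" else 0.0 for s in subjects]
        )[self.subject_index]
        cols["cyp3a5_carrier"] = (cols["genotype_cyp3a5_recipient"] > 0).astype(float)
        cols["cyp3a5_carrier_donor"] = (cols["genotype_cyp3a5_donor"] > 0).astype(float)
        self.columns = cols

    def col(self, name: str) -> np.ndarray:
        try:
            return self.columns[name]
        except KeyError:
            raise KeyError(f"unknown covariate column {name!r}") from None

    def per_subject_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts)

    def expand(self, per_subject: np.ndarray) -> np.ndarray:
        """Broadcast a per-subject vector/matrix onto observations."""
        return per_subject[self.subject_index]


# ---------------------------------------------------------------------------
# frame conversion (round-trippable with io.read_dataset / io.write_dataset)


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    records = []
    for s in subjects:
        base = {name: getattr(s, name) for name in _SUBJ_COLS}
        for r in sorted(s.rows, key=lambda r: r.pod):
            rec = dict(base)
            rec.update({name: getattr(r, name) for name in _ROW_COLS})
            records.append(rec)
    frame = pd.DataFrame.from_records(records)
    frame["at_steady_state"] = frame["at_steady_state"].astype(int)
    return frame


def frame_to_subjects(frame: pd.DataFrame) -> list[SubjectRecord]:
    subjects = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        first = grp.iloc[0]
        kw = {name: first[name] for name in _SUBJ_COLS if name != "subject_id"}
        for k in kw:
            if k.startswith("genotype_"):
                kw[k] = int(kw[k])
        rows = []
        for _, rec in grp.sort_values("pod").iterrows():
            rkw = {name: rec[name] for name in _ROW_COLS}
            for k in ("taf", "wuzhi", "ccb", "ppi", "mmf"):
                rkw[k] = int(rkw[k])
            rkw["at_steady_state"] = bool(int(rec["at_steady_state"]))
            rows.append(ObservationRow(**rkw))
        subjects.append(SubjectRecord(subject_id=str(sid), rows=rows, **kw))
    return subjects
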