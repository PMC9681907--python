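"""Synthetic TDM cohort generator.

Emulates the statistical structure of an adult liver-transplant cohort
under routine tacrolimus therapeutic drug monitoring: covariates drawn
from moment-matched truncated (log-)normal distributions, genotypes from
observed genotype frequencies, and dose-titration feedback that adjusts
the daily dose toward a target trough window of 8-12 ng/ml.

The trough/dose pairs are generated exactly under the chosen structural
truth so that downstream estimation is a well-posed recovery problem:

* MM truth -- the stored trough is the model-consistent steady state for
  the administered (titrated) dose given the subject's eta; the residual
  is realized on the recorded daily dose, the MM model's dependent
  variable.
* THEORY truth -- the stored trough is the predicted whole-blood trough
  for the administered dose times a proportional residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .datamodel import ObservationRow, SubjectRecord
from .models import (
    ModelSpec,
    individual_param,
    mm_c0_solve,
    plasma_to_blood,
    ss_trough_plasma,
)

__all__ = [
    "CohortSpec",
    "TruthModel",
    "sample_covariates",
    "sample_genotypes",
    "simulate_tdm_course",
    "generate_dataset",
    "cockcroft_gault",
    "hwe_test",
]


# covariate marginals: name -> (kind, mean, sd, lo, hi)
# right-skewed labs (mean/median ratio > 1.3) use a truncated log-normal
_DEFAULT_COVARIATES: dict[str, tuple[str, float, float, float, float]] = {
    "age": ("normal", 50.68, 9.71, 18.0, 74.0),
    "height": ("normal", 1.69, 0.06, 1.54, 1.84),
    "weight": ("normal", 64.54, 11.85, 40.0, 104.0),
    "ffm": ("normal", 50.27, 8.50, 28.87, 68.47),
    "graft_weight": ("normal", 1310.35, 207.42, 603.0, 2200.0),
    "hct": ("normal", 31.78, 4.98, 15.4, 53.6),
    "alb": ("normal", 37.24, 4.05, 20.0, 51.0),
    "alt": ("lognormal", 138.99, 183.99, 4.0, 1765.0),
    "ast": ("lognormal", 83.54, 143.15, 9.0, 2547.0),
    "tbil": ("lognormal", 88.32, 90.11, 5.1, 786.3),
    "scr": ("normal", 62.15, 28.47, 19.0, 400.0),
}

# genotype counts (0/1/2 variant or *1 alleles) for recipients and donors
_DEFAULT_GENOTYPES: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "cyp3a5": ((93, 71, 12), (81, 84, 11)),
    "cyp3a4_1g": ((99, 61, 16), (92, 75, 9)),
    "sumo4": ((83, 79, 14), (86, 74, 16)),
    "nr112": ((37, 116, 23), (54, 86, 36)),
}


@dataclass
class CohortSpec:
    """Cohort-level sampling configuration (defaults emulate the study)."""

    n_subjects: int = 176
    n_female: int = 26
    covariates: dict[str, tuple[str, float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES)
    )
    genotype_counts: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = field(
        default_factory=lambda: dict(_DEFAULT_GENOTYPES)
    )
    taf_prevalence: float = 56.0 / 176.0
    comedication_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "wuzhi": 112 / 906,
            "ccb": 65 / 906,
            "ppi": 645 / 906,
            "mmf": 53 / 906,
        }
    )
    visits_poisson_mean: float = 4.0  # visits = max(2, 1 + Poisson(mean)), median 5
    first_pod_range: tuple[int, int] = (3, 6)
    pod_max: int = 72


@dataclass
class TruthModel:
    """Data-generating model plus the dose-titration policy."""

    spec: ModelSpec
    starting_doses: tuple[float, ...] = (1.0, 1.5, 2.0)
    target_window: tuple[float, float] = (8.0, 12.0)
    dose_grid: float = 0.25
    max_step_fraction: float = 0.5  # cap on relative dose change per visit
    max_step_mg: float = float("inf")  # optional absolute cap per adjustment
    assay_cv: float = 0.10  # noise on the trough the clinician titrates on


# ---------------------------------------------------------------------------
# moment-matched truncated samplers


def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Solve for (mu, sigma) of the parent normal so that the truncated
    distribution has the requested mean and SD."""

    def eqs(p):
        mu, lsig = p
        sig = np.exp(lsig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(eqs, [mean, np.log(sd)], method="hybr")
    mu, lsig = sol.x
    return float(mu), float(np.exp(lsig))


def _trunc_lognorm_moments(mu: float, sig: float, lo: float, hi: float):
    a, b = (np.log(lo) - mu) / sig, (np.log(hi) - mu) / sig
    z = stats.norm.cdf(b) - stats.norm.cdf(a)
    m1 = np.exp(mu + sig**2 / 2) * (stats.norm.cdf(b - sig) - stats.norm.cdf(a - sig)) / z
    m2 = (
        np.exp(2 * mu + 2 * sig**2)
        * (stats.norm.cdf(b - 2 * sig) - stats.norm.cdf(a - 2 * sig))
        / z
    )
    return m1, np.sqrt(max(m2 - m1**2, 1e-12))


def _trunc_lognorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    sig0 = np.sqrt(np.log(1 + (sd / mean) ** 2))
    mu0 = np.log(mean) - sig0**2 / 2

    def eqs(p):
        mu, lsig = p
        m, s = _trunc_lognorm_moments(mu, np.exp(lsig), lo, hi)
        return [m - mean, s - sd]

    sol = optimize.root(eqs, [mu0, np.log(sig0)], method="hybr")
    mu, lsig = sol.x
    return float(mu), float(np.exp(lsig))


def _sample_marginal(
    kind: str, mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if kind == "normal":
        mu, sig = _truncnorm_params(mean, sd, lo, hi)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=n)
        return mu + sig * stats.norm.ppf(u)
    if kind == "lognormal":
        mu, sig = _trunc_lognorm_params(mean, sd, lo, hi)
        a, b = (np.log(lo) - mu) / sig, (np.log(hi) - mu) / sig
        u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=n)
        return np.exp(mu + sig * stats.norm.ppf(u))
    raise ValueError(f"unknown marginal kind {kind!r}")


def cockcroft_gault(age, weight, scr, female) -> np.ndarray:
    """Creatinine clearance (ml/min) with creatinine in umol/L:
    (140 - age) * weight / (0.818 * SCR), times 0.85 for women."""
    base = (140.0 - np.asarray(age)) * np.asarray(weight) / (0.818 * np.asarray(scr))
    return base * np.where(np.asarray(female, dtype=bool), 0.85, 1.0)


# ---------------------------------------------------------------------------
# sampling operations


def sample_covariates(cohort: CohortSpec, seed: int) -> list[SubjectRecord]:
    """Draw demographic / baseline laboratory covariates for a cohort.

    Creatinine clearance is computed from the sampled age, weight and
    creatinine with the Cockcroft-Gault formula, never sampled directly.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_subjects
    draws = {
        name: _sample_marginal(*dist, n, rng) for name, dist in cohort.covariates.items()
    }
    female = np.zeros(n, dtype=bool)
    female[rng.choice(n, size=min(cohort.n_female, n), replace=False)] = True
    subjects = []
    for i in range(n):
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                sex="female" if female[i] else "male",
                age=float(draws["age"][i]),
                weight=float(draws["weight"][i]),
                height=float(draws["height"][i]),
                ffm=float(draws["ffm"][i]),
                graft_weight=float(draws["graft_weight"][i]),
            )
        )
        # stash baseline labs for the TDM course on the instance
        subjects[-1]._baseline = {  # type: ignore[attr-defined]
            k: float(draws[k][i]) for k in ("hct", "alb", "alt", "ast", "tbil", "scr")
        }
    return subjects


def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Pearson chi-squared test of Hardy-Weinberg proportions for one
    biallelic locus; ``counts`` are (hom-ref, het, hom-alt) genotypes."""
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    p = (2 * n0 + n1) / (2 * n)  # reference-allele frequency
    expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n0, n1, n2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((observed - expected) ** 2 / np.where(expected > 0, expected, np.nan)))
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def sample_genotypes(
    cohort: CohortSpec, subjects: list[SubjectRecord], seed: int
) -> dict[str, dict[str, tuple[float, float]]]:
    """Assign recipient and donor genotypes from the configured genotype
    frequencies (independently per locus and per role) and return a
    Hardy-Weinberg report {locus: {role: (chi2, p)}}."""
    rng = np.random.default_rng(seed)
    n = len(subjects)
    report: dict[str, dict[str, tuple[float, float]]] = {}
    for locus, (rec_counts, don_counts) in cohort.genotype_counts.items():
        report[locus] = {}
        for role, counts in (("recipient", rec_counts), ("donor", don_counts)):
            probs = np.asarray(counts, dtype=float)
            probs = probs / probs.sum()
            draws = rng.choice(3, size=n, p=probs)
            attr = f"genotype_{locus}_{role}"
            for s, g in zip(subjects, draws):
                setattr(s, attr, int(g))
            tallied = tuple(int(np.sum(draws == k)) for k in range(3))
            report[locus][role] = hwe_test(tallied)
    return report


# ---------------------------------------------------------------------------
# TDM course simulation


def _row_covariates(subject: SubjectRecord, pod: float, rng: np.random.Generator) -> dict:
    """Time-varying labs: slow first-order recovery toward normal ranges
    anchored at the cohort-median day (POD 10), with log-normal noise."""
    base = getattr(subject, "_baseline")
    hct = base["hct"] * np.exp(0.004 * (pod - 10.0)) * np.exp(rng.normal(0, 0.05))
    ast = base["ast"] * np.exp(-0.010 * (pod - 10.0)) * np.exp(rng.normal(0, 0.15))
    alt = base["alt"] * np.exp(-0.010 * (pod - 10.0)) * np.exp(rng.normal(0, 0.15))
    tbil = base["tbil"] * np.exp(-0.012 * (pod - 10.0)) * np.exp(rng.normal(0, 0.15))
    alb = base["alb"] * np.exp(rng.normal(0, 0.04))
    scr = base["scr"] * np.exp(rng.normal(0, 0.06))
    return {
        "hct": float(np.clip(hct, 12.0, 60.0)),
        "ast": float(np.clip(ast, 3.0, 3000.0)),
        "alt": float(np.clip(alt, 3.0, 3000.0)),
        "tbil": float(np.clip(tbil, 2.0, 900.0)),
        "alb": float(np.clip(alb, 15.0, 55.0)),
        "scr": float(np.clip(scr, 15.0, 500.0)),
    }


def _steroid_dose(pod: float) -> float:
    """Methylprednisolone-equivalent taper after transplantation."""
    if pod <= 3:
        return 160.0
    if pod <= 5:
        return 80.0
    if pod <= 7:
        return 40.0
    if pod <= 10:
        return 20.0
    if pod <= 13:
        return 12.0
    if pod <= 16:
        return 8.0
    return 4.0


def _round_grid(x: float, step: float) -> float:
    return max(step, round(x / step) * step)


def _titrate(dd_admin: float, observed: float, truth: "TruthModel", spec: ModelSpec) -> float:
    """One proportional dose adjustment toward the window midpoint,
    bounded by relative and absolute step caps and the dose grid."""
    target_mid = 0.5 * (truth.target_window[0] + truth.target_window[1])
    proposal = dd_admin * target_mid / max(observed, 0.3)
    lo = max(dd_admin * (1 - truth.max_step_fraction), dd_admin - truth.max_step_mg)
    hi = min(dd_admin * (1 + truth.max_step_fraction), dd_admin + truth.max_step_mg)
    out = _round_grid(float(np.clip(proposal, lo, hi)), truth.dose_grid)
    if spec.model_id == "MM":
        out = min(out, _round_grid(0.92 * spec.fixed_effects["vm"], truth.dose_grid))
    return out


def _clean_trough(
    spec: ModelSpec,
    cov_values: dict,
    eta_by_param: dict,
    dd_admin: float,
    pod: float,
    truth: "TruthModel",
) -> float:
    """Noise-free steady-state trough for the administered dose."""
    if spec.model_id == "MM":
        vm = spec.fixed_effects["vm"]
        km_i = float(
            individual_param(
                spec.fixed_effects["km"], spec.effects_on("km"), cov_values,
                eta_by_param.get("km", 0.0),
            )
        )
        dd = min(dd_admin, 0.92 * vm)
        return float(mm_c0_solve(vm, km_i, dd, pod, spec.time_factor_enabled))
    cl_i = float(
        individual_param(
            spec.fixed_effects["cl"], spec.effects_on("cl"), cov_values,
            eta_by_param.get("cl", 0.0),
        )
    )
    v_i = float(
        individual_param(
            spec.fixed_effects["v"], spec.effects_on("v"), cov_values,
            eta_by_param.get("v", 0.0),
        )
    )
    cp = float(ss_trough_plasma(cl_i, v_i, spec.fixed_effects["ka"], dd_admin / 2.0))
    hct_frac = cov_values["hct"] / 100.0 if spec.hct_as_fraction else cov_values["hct"]
    return float(plasma_to_blood(cp, hct_frac, spec.partition))


def simulate_tdm_course(
    subject: SubjectRecord,
    truth: TruthModel,
    seed: int,
    eta: np.ndarray | None = None,
    residual_noise: bool = True,
) -> list[ObservationRow]:
    """Simulate one subject's dose-titration course under the truth model.

    The dose starts low (0.5-1 mg q12h) and at every visit is multiplied
    by (target midpoint / latest trough), rounded to the dose grid and
    capped at +/-50% change per step.
    """
    rng = np.random.default_rng(seed)
    spec = truth.spec
    omega = np.array([spec.random_effects[k] for k in spec.eta_names])
    if eta is None:
        eta = rng.standard_normal(len(omega)) * omega
    eta = np.asarray(eta, dtype=float)
    eta_by_param = dict(zip(spec.eta_names, eta))

    n_visits = max(2, 1 + rng.poisson(4.0))
    pod = float(rng.integers(3, 7))
    dd_admin = float(rng.choice(truth.starting_doses))
    carrier = 1.0 if subject.genotype_cyp3a5_recipient > 0 else 0.0
    taf = float(getattr(subject, "_taf", 0))  # assigned at cohort level

    # MM only: troughs drawn before the dose has been constant for >=3
    # doses are titrated on clinically but never enter the analysis
    # dataset; two such unrecorded adjustment steps move the first
    # recorded dose away from the additive-error truncation region.  The
    # clinician reacts to a measured trough (assay noise), never to the
    # noise-free model value.
    if spec.model_id == "MM":
        for warm_pod in (1.0, 2.0):
            covs = _row_covariates(subject, warm_pod, rng)
            cov_values = {
                "pod": warm_pod,
                "hct": covs["hct"],
                "ast": covs["ast"],
                "tbil": covs["tbil"],
                "cyp3a5_carrier": carrier,
                "taf": taf,
                "daily_dose": dd_admin,
            }
            obs = _clean_trough(spec, cov_values, eta_by_param, dd_admin, warm_pod, truth)
            obs *= 1.0 + rng.normal(0.0, truth.assay_cv)
            dd_admin = _titrate(dd_admin, obs, truth, spec)

    rows: list[ObservationRow] = []
    res = spec.residual
    for _ in range(n_visits):
        covs = _row_covariates(subject, pod, rng)
        cov_values = {
            "pod": pod,
            "hct": covs["hct"],
            "ast": covs["ast"],
            "tbil": covs["tbil"],
            "cyp3a5_carrier": carrier,
            "taf": taf,
            "daily_dose": dd_admin,
        }
        if spec.model_id == "MM":
            vm = spec.fixed_effects["vm"]
            km_i = float(
                individual_param(
                    spec.fixed_effects["km"],
                    spec.effects_on("km"),
                    cov_values,
                    eta_by_param.get("km", 0.0),
                )
            )
            dd_admin = min(dd_admin, _round_grid(0.92 * vm, truth.dose_grid))
            c0 = float(
                mm_c0_solve(vm, km_i, dd_admin, pod, spec.time_factor_enabled)
            )
            if residual_noise:
                for _ in range(100):
                    e1 = rng.normal(0, res.sigma1) if res.form != "additive" else 0.0
                    e2 = rng.normal(0, res.sigma2 if res.form == "combined" else res.sigma1)
                    if res.form == "proportional":
                        dd_row = dd_admin * (1 + e1)
                    else:
                        dd_row = dd_admin * (1 + e1) + e2
                    if dd_row > 0.05:
                        break
            else:
                dd_row = dd_admin
            # the clinician titrates on a measured trough, not the exact
            # steady-state value
            observed = c0 * (1.0 + rng.normal(0.0, truth.assay_cv)) if residual_noise else c0
            row_dose, row_c0 = dd_row, c0
        else:
            cl_i = float(
                individual_param(
                    spec.fixed_effects["cl"],
                    spec.effects_on("cl"),
                    cov_values,
                    eta_by_param.get("cl", 0.0),
                )
            )
            v_i = float(
                individual_param(
                    spec.fixed_effects["v"],
                    spec.effects_on("v"),
                    cov_values,
                    eta_by_param.get("v", 0.0),
                )
            )
            cp = float(ss_trough_plasma(cl_i, v_i, spec.fixed_effects["ka"], dd_admin / 2.0))
            hct_frac = covs["hct"] / 100.0 if spec.hct_as_fraction else covs["hct"]
            cwb = float(plasma_to_blood(cp, hct_frac, spec.partition))
            if residual_noise:
                for _ in range(100):
                    obs = cwb * (1 + rng.normal(0, res.sigma1))
                    if obs > 0:
                        break
            else:
                obs = cwb
            observed = obs
            row_dose, row_c0 = dd_admin, obs

        rows.append(
            ObservationRow(
                pod=pod,
                daily_dose=row_dose,
                c0=row_c0,
                hct=covs["hct"],
                ast=covs["ast"],
                alt=covs["alt"],
                tbil=covs["tbil"],
                alb=covs["alb"],
                scr=covs["scr"],
                clcr=float(
                    cockcroft_gault(subject.age, subject.weight, covs["scr"], subject.sex == "female")
                ),
                taf=int(taf),
                steroid_dose=_steroid_dose(pod),
                wuzhi=int(getattr(subject, "_wuzhi", 0)),
                ccb=int(getattr(subject, "_ccb", 0)),
                ppi=int(getattr(subject, "_ppi", 0)),
                mmf=int(getattr(subject, "_mmf", 0)),
                at_steady_state=True,
            )
        )

        # titration toward the target midpoint, grid-rounded and step-capped;
        # the dose is left alone while the trough sits inside the window
        if not truth.target_window[0] <= observed <= truth.target_window[1]:
            dd_admin = _titrate(dd_admin, observed, truth, spec)
        pod += float(2 + rng.poisson(1.0))
        if pod > 72:
            break
    return rows


def generate_dataset(
    cohort: CohortSpec,
    truth: TruthModel,
    seed: int,
) -> tuple[list[SubjectRecord], dict]:
    """Full cohort: covariates + genotypes + TDM trajectories.

    Returns the subjects and a ground-truth sidecar with the per-subject
    eta draws, the truth spec name and the seeds used, so that recovery
    experiments can compare estimates against the generating values.
    """
    rng = np.random.default_rng(seed)
    subjects = sample_covariates(cohort, seed=int(rng.integers(2**31 - 1)))
    hwe = sample_genotypes(cohort, subjects, seed=int(rng.integers(2**31 - 1)))
    omega = np.array([truth.spec.random_effects[k] for k in truth.spec.eta_names])
    etas = {}
    for s in subjects:
        s._taf = int(rng.random() < cohort.taf_prevalence)  # type: ignore[attr-defined]
        for med, p in cohort.comedication_prevalence.items():
            setattr(s, f"_{med}", int(rng.random() < p))
        eta = rng.standard_normal(len(omega)) * omega
        etas[s.subject_id] = eta
        s.rows = simulate_tdm_course(
            s, truth, seed=int(rng.integers(2**31 - 1)), eta=eta
        )
    ground_truth = {
        "truth_name": truth.spec.name,
        "seed": seed,
        "eta": {k: v.tolist() for k, v in etas.items()},
        "hwe": hwe,
    }
    return subjects, ground_truth
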