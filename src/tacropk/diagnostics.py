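"""Model evaluation: prediction errors, bootstrap, pvcVPC and NPDE.

All diagnostics operate on the dataset's own design (regressors and
covariates fixed) and use :func:`tacropk.models.simulate_dv` for
simulation-based checks, so a model evaluated against data simulated
from itself is exactly calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import FlatData, SubjectRecord
from .estimation import FitResult, fit_model
from .models import ModelSpec, predict, simulate_dv

__all__ = [
    "PredErrorSummary",
    "prediction_error_metrics",
    "BootstrapResult",
    "bootstrap_run",
    "VpcSummary",
    "pvc_vpc",
    "NpdeSummary",
    "npde_run",
]


# ---------------------------------------------------------------------------
# prediction-error metrics


@dataclass
class PredErrorSummary:
    """Population (PRED) and individual (IPRED) percent prediction errors.

    MDPE/MAPE are median signed / median absolute percent errors; F20 and
    F30 the percentages of absolute errors within 20% and 30% (boundary
    inclusive).
    """

    mdpe: float
    mape: float
    f20: float
    f30: float
    mdipe: float = float("nan")
    maipe: float = float("nan")
    if20: float = float("nan")
    if30: float = float("nan")


def _pe_stats(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float, float, float]:
    pe = (pred - obs) / obs * 100.0
    ape = np.abs(pe)
    return (
        float(np.median(pe)),
        float(np.median(ape)),
        float(np.mean(ape <= 20.0) * 100.0),
        float(np.mean(ape <= 30.0) * 100.0),
    )


def prediction_error_metrics(
    obs: np.ndarray, pred: np.ndarray, ipred: np.ndarray | None = None
) -> PredErrorSummary:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("obs and pred must be equal-length non-empty arrays")
    if np.any(obs <= 0):
        raise ValueError("observations must be positive for percent errors")
    mdpe, mape, f20, f30 = _pe_stats(obs, pred)
    out = PredErrorSummary(mdpe, mape, f20, f30)
    if ipred is not None:
        out.mdipe, out.maipe, out.if20, out.if30 = _pe_stats(obs, np.asarray(ipred, float))
    return out


# ---------------------------------------------------------------------------
# nonparametric bootstrap (resampling by subject)


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    medians: dict[str, float]
    ci_lo: dict[str, float]
    ci_hi: dict[str, float]
    bias_percent: dict[str, float]
    samples: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def convergence_rate(self) -> float:
        return self.n_converged / self.n_requested

    @property
    def low_convergence_warning(self) -> bool:
        return self.convergence_rate < 0.5


def bootstrap_run(
    subjects: list[SubjectRecord],
    spec: ModelSpec,
    original_fit: FitResult,
    n: int = 1000,
    seed: int = 0,
    maxiter: int = 200,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the parameter estimates.

    Each replicate resamples subjects with replacement to the original
    subject count and refits ``spec`` (initialized at the original
    estimates).  Replicates that fail to converge are counted but
    excluded from the percentiles.  bias% = (bootstrap median -
    original) / original * 100.
    """
    rng = np.random.default_rng(seed)
    names = original_fit.param_names
    draws: dict[str, list[float]] = {k: [] for k in names}
    n_conv = 0
    for _ in range(n):
        idx = rng.integers(0, len(subjects), size=len(subjects))
        resampled = [subjects[i] for i in idx]
        data = FlatData(resampled)
        try:
            fit = fit_model(data, original_fit.spec, compute_rse=False, maxiter=maxiter)
        except Exception:  # noqa: BLE001 - non-convergence is an outcome
            continue
        if not np.isfinite(fit.ofv):
            continue
        n_conv += 1
        for k in names:
            draws[k].append(fit.estimates[k])
    medians, lo, hi, bias = {}, {}, {}, {}
    for k in names:
        arr = np.asarray(draws[k])
        if arr.size:
            medians[k] = float(np.median(arr))
            lo[k] = float(np.percentile(arr, 2.5))
            hi[k] = float(np.percentile(arr, 97.5))
            orig = original_fit.estimates[k]
            bias[k] = 100.0 * (medians[k] - orig) / orig if orig != 0 else float("nan")
        else:
            medians[k] = lo[k] = hi[k] = bias[k] = float("nan")
    return BootstrapResult(
        n_requested=n,
        n_converged=n_conv,
        medians=medians,
        ci_lo=lo,
        ci_hi=hi,
        bias_percent=bias,
        samples={k: np.asarray(v) for k, v in draws.items()},
    )


# ---------------------------------------------------------------------------
# prediction- and variability-corrected VPC


@dataclass
class VpcSummary:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    obs_percentiles: np.ndarray  # (n_bins, 3): 10th, 50th, 90th of corrected obs
    sim_ci: np.ndarray  # (n_bins, 3, 2): 95% CI of each percentile across sims
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0)

    def coverage(self) -> float:
        """Fraction of bin-percentile points inside their simulated 95% CI."""
        inside = (self.obs_percentiles >= self.sim_ci[..., 0]) & (
            self.obs_percentiles <= self.sim_ci[..., 1]
        )
        return float(np.mean(inside))


def _equal_count_bins(x: np.ndarray, n_bins: int, min_count: int = 5) -> np.ndarray:
    qs = np.linspace(0, 100, n_bins + 1)
    edges = np.unique(np.percentile(x, qs))
    # merge sparse bins with their left neighbor
    while len(edges) > 2:
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.where(counts < min_count)[0]
        if small.size == 0:
            break
        j = small[0]
        edges = np.delete(edges, j if j > 0 else 1)
    return edges


def pvc_vpc(
    data: FlatData,
    spec: ModelSpec,
    n_sim: int = 1000,
    n_bins: int = 8,
    seed: int = 0,
) -> VpcSummary:
    """Prediction- and variability-corrected visual predictive check.

    Observations and simulated replicates are binned on postoperative
    day.  Within each bin every value is prediction-corrected by
    (bin-median typical prediction / its own typical prediction) and the
    centered values are variability-corrected by the ratio of the
    across-bin median simulated spread to the bin's simulated spread.
    The summary holds the corrected observed 10th/50th/90th percentiles
    per bin and the simulation-based 95% CIs of those percentiles.
    """
    rng = np.random.default_rng(seed)
    pod = data.col("pod")
    y = data.col(spec.dv_column)
    pred_typ = predict(spec, data, np.zeros((data.n_subjects, spec.n_eta)) if spec.n_eta else None)
    sims = simulate_dv(spec, data, rng, n_replicates=n_sim)

    edges = _equal_count_bins(pod, n_bins)
    idx = np.clip(np.searchsorted(edges, pod, side="right") - 1, 0, len(edges) - 2)
    n_b = len(edges) - 1
    pcts = (10.0, 50.0, 90.0)

    # prediction correction
    pc_y = np.empty_like(y)
    pc_sims = np.empty_like(sims)
    bin_spread = np.empty(n_b)
    for b in range(n_b):
        m = idx == b
        med_pred = np.median(pred_typ[m])
        ratio = med_pred / pred_typ[m]
        pc_y[m] = y[m] * ratio
        pc_sims[:, m] = sims[:, m] * ratio
        bin_spread[b] = np.median(np.abs(pc_sims[:, m] - np.median(pc_sims[:, m])))
    # variability correction toward the typical (across-bin median) spread
    target_spread = np.median(bin_spread[bin_spread > 0]) if np.any(bin_spread > 0) else 1.0
    for b in range(n_b):
        m = idx == b
        if bin_spread[b] <= 0:
            continue
        factor = target_spread / bin_spread[b]
        center = np.median(pc_sims[:, m])
        pc_y[m] = center + (pc_y[m] - center) * factor
        pc_sims[:, m] = center + (pc_sims[:, m] - center) * factor

    obs_p = np.empty((n_b, 3))
    ci = np.empty((n_b, 3, 2))
    for b in range(n_b):
        m = idx == b
        obs_p[b] = np.percentile(pc_y[m], pcts)
        sim_p = np.percentile(pc_sims[:, m], pcts, axis=1).T  # (n_sim, 3)
        ci[b, :, 0] = np.percentile(sim_p, 2.5, axis=0)
        ci[b, :, 1] = np.percentile(sim_p, 97.5, axis=0)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return VpcSummary(edges, mids, obs_p, ci, pcts)


# ---------------------------------------------------------------------------
# normalized prediction distribution errors


@dataclass
class NpdeSummary:
    npde: np.ndarray
    p_mean: float
    p_variance: float
    p_normality: float
    p_global: float
    n_regularized: int = 0

    @property
    def global_ok(self) -> bool:
        return self.p_global >= 0.05


def npde_run(
    data: FlatData,
    spec: ModelSpec,
    n_sim: int = 2000,
    seed: int = 0,
) -> NpdeSummary:
    """Normalized prediction distribution errors with the global test.

    Per subject, the simulated observation matrix is mean-centered and
    decorrelated with the lower-triangular Cholesky factor of its
    empirical covariance; the observed vector receives the identical
    transform.  The rank of each decorrelated observation among its
    decorrelated simulations (with a 1/(2*n_sim) continuity correction)
    is mapped through the standard-normal quantile function.  The global
    test Bonferroni-combines a t-test for zero mean, a chi-squared test
    for unit variance and a Shapiro-Wilk normality test.
    """
    rng = np.random.default_rng(seed)
    sims = simulate_dv(spec, data, rng, n_replicates=n_sim)  # (K, n_obs)
    y = data.col(spec.dv_column)
    npde = np.empty(data.n_obs)
    n_reg = 0
    for i in range(data.n_subjects):
        s = data.starts[i]
        n_i = data.counts[i]
        sl = slice(s, s + n_i)
        sim_i = sims[:, sl]  # (K, n_i)
        mu = sim_i.mean(axis=0)
        if n_i == 1:
            sd = sim_i.std(axis=0, ddof=1)
            dec_obs = (y[sl] - mu) / sd
            dec_sim = (sim_i - mu) / sd
        else:
            cov = np.cov(sim_i, rowvar=False)
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                cov = cov + 1e-8 * np.eye(n_i) * np.trace(cov) / n_i
                L = np.linalg.cholesky(cov)
                n_reg += 1
            dec_obs = np.linalg.solve(L, y[sl] - mu)
            dec_sim = np.linalg.solve(L, (sim_i - mu).T).T
        ranks = np.mean(dec_sim < dec_obs, axis=0)
        ranks = np.clip(ranks, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        npde[sl] = stats.norm.ppf(ranks)

    t_p = float(stats.ttest_1samp(npde, 0.0).pvalue)
    n = npde.size
    s2 = float(np.var(npde, ddof=1))
    chi = (n - 1) * s2
    var_p = float(2 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1)))
    sw_p = float(stats.shapiro(npde if n <= 5000 else rng.choice(npde, 5000, replace=False)).pvalue)
    p_global = min(1.0, 3.0 * min(t_p, var_p, sw_p))
    return NpdeSummary(npde, t_p, var_p, sw_p, p_global, n_reg)
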