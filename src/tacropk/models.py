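"""Structural models for tacrolimus dose--trough data.

Two model families are implemented:

* **MM** -- an empirical Michaelis--Menten relation between the total daily
  dose ``DD`` (the dependent variable) and the steady-state whole-blood
  trough ``C0``::

      DD = Vm * C0 / (f * Km_i + C0),     f = 10 / min(POD, 10)

  ``Vm`` (mg/day) is the maximum steady-state dose rate, ``Km_i`` (ng/ml)
  the trough at the half-maximal dose rate for subject *i* after covariate
  adjustment, and ``f`` an optional early-postoperative time factor that
  inflates the effective Km before day 10.

* **THEORY** -- a one-compartment plasma model with first-order absorption
  and elimination fitted to whole-blood troughs.  Whole blood and plasma
  are linked by saturable binding of tacrolimus to erythrocytes::

      Cwb = Cp + Cp * HCT * Bmax / (Cp + KD)

  with Bmax = 418 ug/L and KD = 3.8 ug/L and HCT as a volume fraction.
  Disposition parameters (CL_pl/F, V_pl/F) act on plasma concentrations;
  the observation model converts the plasma trough back to whole blood
  with the subject's hematocrit.

Inter-subject variability is exponential, ``P_i = TV(P) * exp(eta_i)``;
residual error may be additive, proportional or combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import FlatData

__all__ = [
    "CovariateEffect",
    "ResidualModel",
    "PartitionConstants",
    "ModelSpec",
    "covariate_factor",
    "individual_param",
    "mm_dose_pred",
    "mm_c0_solve",
    "plasma_to_blood",
    "blood_to_plasma",
    "ss_trough_plasma",
    "residual_variance",
    "predict",
    "simulate_dv",
    "mm_base",
    "mm_final",
    "theory_base",
    "theory_final",
    "preset",
]

ArrayLike = "np.ndarray | float"

_FORMS = ("linear", "exponential", "power", "scale", "saturable_emax")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate term on one structural parameter.

    ``power``/``exponential`` normalize the covariate to ``reference``
    (the cohort median); ``scale`` applies ``1 + theta * cov`` to a 0/1
    (or allele-count) covariate; ``saturable_emax`` is the Emax-in-dose
    factor ``theta * cov / (theta2 + cov)``; ``linear`` contributes the
    additive term ``theta * cov / reference``.
    """

    parameter: str
    covariate: str
    form: str
    theta: float
    reference: float = 1.0
    theta2: float | None = None

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form in ("linear", "exponential", "power") and not self.reference > 0:
            raise ValueError("continuous forms need a positive reference value")
        if self.form == "saturable_emax" and self.theta2 is None:
            raise ValueError("saturable_emax needs theta2 (the half-effect covariate value)")

    @property
    def label(self) -> str:
        return f"{self.parameter}~{self.covariate}:{self.form}"

    @property
    def n_theta(self) -> int:
        return 2 if self.form == "saturable_emax" else 1


def covariate_factor(effect: CovariateEffect, cov_value):
    """Evaluate one covariate term.

    Returns ``("mult", m)`` for multiplicative forms or ``("add", a)`` for
    the linear form; ``m``/``a`` follow the shape of ``cov_value``.
    """
    x = np.asarray(cov_value, dtype=float)
    th = effect.theta
    if effect.form == "power":
        if np.any(x <= 0):
            raise ValueError(f"power form needs positive covariate values ({effect.label})")
        return "mult", (x / effect.reference) ** th
    if effect.form == "exponential":
        return "mult", np.exp(th * x / effect.reference)
    if effect.form == "scale":
        return "mult", 1.0 + th * x
    if effect.form == "saturable_emax":
        return "mult", th * x / (effect.theta2 + x)
    # linear
    return "add", th * x / effect.reference


def individual_param(tv, effects, cov_values, eta=0.0):
    """Realized parameter: ``(tv + additive terms) * prod(multipliers) * exp(eta)``.

    ``cov_values`` maps covariate names to scalars or arrays.
    """
    base = np.asarray(tv, dtype=float) + 0.0
    mult = 1.0
    for eff in effects:
        kind, val = covariate_factor(eff, cov_values[eff.covariate])
        if kind == "add":
            base = base + val
        else:
            mult = mult * val
    return base * mult * np.exp(eta)


# ---------------------------------------------------------------------------
# Michaelis-Menten dose <-> trough algebra


def _time_factor(pod, enabled: bool):
    if not enabled:
        return np.ones_like(np.asarray(pod, dtype=float))
    theta = np.clip(np.asarray(pod, dtype=float), None, 10.0)
    return 10.0 / theta


def mm_dose_pred(vm, km_i, c0, pod=10.0, time_factor_enabled: bool = False):
    """Daily dose sustaining trough ``c0``: ``Vm*C0 / (f*Km + C0)`` (mg/day)."""
    f = _time_factor(pod, time_factor_enabled)
    c0 = np.asarray(c0, dtype=float)
    return vm * c0 / (f * km_i + c0)


def mm_c0_solve(vm, km_i, dd, pod=10.0, time_factor_enabled: bool = False):
    """Steady-state trough at dose ``dd``: exact inverse of :func:`mm_dose_pred`.

    Raises for ``dd >= vm`` -- doses at or above the maximum elimination
    capacity have no steady state (accumulation regime).
    """
    dd = np.asarray(dd, dtype=float)
    if np.any(dd >= vm):
        raise ValueError("daily dose at or above Vm: no steady state (accumulation)")
    if np.any(dd <= 0):
        raise ValueError("daily dose must be positive")
    f = _time_factor(pod, time_factor_enabled)
    return f * km_i * dd / (vm - dd)


# ---------------------------------------------------------------------------
# whole-blood <-> plasma partition (saturable erythrocyte binding)


@dataclass(frozen=True)
class PartitionConstants:
    """Erythrocyte binding capacity and affinity (ug/L == ng/ml)."""

    b_max: float = 418.0
    k_d: float = 3.8


DEFAULT_PARTITION = PartitionConstants()


def plasma_to_blood(cp, hct, consts: PartitionConstants = DEFAULT_PARTITION):
    """Whole-blood concentration from plasma, ``hct`` as a fraction."""
    cp = np.asarray(cp, dtype=float)
    return cp + cp * hct * consts.b_max / (cp + consts.k_d)


def blood_to_plasma(cwb, hct, consts: PartitionConstants = DEFAULT_PARTITION):
    """Plasma concentration from whole blood: positive root of the binding
    quadratic ``cp^2 + cp*(KD + hct*Bmax - cwb) - KD*cwb = 0``."""
    cwb = np.asarray(cwb, dtype=float)
    b = consts.k_d + hct * consts.b_max - cwb
    # numerically stable quadratic root (b can be large and positive)
    disc = np.sqrt(b * b + 4.0 * consts.k_d * cwb)
    cp = np.where(b >= 0, 2.0 * consts.k_d * cwb / (b + disc), (disc - b) / 2.0)
    return cp


# ---------------------------------------------------------------------------
# one-compartment steady-state trough


def ss_trough_plasma(cl, v, ka, dose_mg, tau_h=12.0, tad_h=12.0):
    """Steady-state plasma concentration (ng/ml) for repeated oral dosing.

    Closed form for a one-compartment model with first-order absorption:
    ``(1000*D/V) * ka/(ka-ke) * [e^(-ke*t)/(1-e^(-ke*tau)) -
    e^(-ka*t)/(1-e^(-ka*tau))]`` with ``ke = CL/V``; the factor 1000
    converts mg/L to ug/L (= ng/ml).  The flip-flop boundary ``ka == ke``
    uses the analytic limit.
    """
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    ke = cl / v
    ka = np.asarray(ka, dtype=float)
    dose = np.asarray(dose_mg, dtype=float)
    scale = 1000.0 * dose / v
    close = np.abs(ka - ke) < 1e-9 * np.maximum(ka, ke)
    with np.errstate(divide="ignore", invalid="ignore"):
        qe = np.exp(-ke * tau_h)
        qa = np.exp(-ka * tau_h)
        general = scale * ka / (ka - ke) * (
            np.exp(-ke * tad_h) / (1.0 - qe) - np.exp(-ka * tad_h) / (1.0 - qa)
        )
    if np.any(close):
        k = np.broadcast_to(ka, np.broadcast_shapes(np.shape(ka), np.shape(ke)))
        q = np.exp(-k * tau_h)
        limit = scale * k * np.exp(-k * tad_h) * (
            tad_h / (1.0 - q) + tau_h * q / (1.0 - q) ** 2
        )
        general = np.where(close, limit, general)
    return general


# ---------------------------------------------------------------------------
# residual error


@dataclass(frozen=True)
class ResidualModel:
    """Residual unexplained variability on the dependent variable.

    ``sigma1`` is the proportional SD (additive SD for the pure additive
    form); ``sigma2`` the additive SD of the combined form.
    """

    form: str  # {additive, proportional, combined}
    sigma1: float
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual form {self.form!r}")


def residual_variance(f, residual: ResidualModel):
    """Variance of the observation given the model prediction ``f``."""
    f = np.asarray(f, dtype=float)
    if residual.form == "additive":
        return np.full_like(f, residual.sigma1**2)
    if residual.form == "proportional":
        return f * f * residual.sigma1**2
    return f * f * residual.sigma1**2 + residual.sigma2**2


# ---------------------------------------------------------------------------
# model specification and vectorized prediction


@dataclass
class ModelSpec:
    """Structural model + covariate effects + variability specification.

    ``fixed_effects`` holds the typical values; ``random_effects`` maps
    parameter names to the SD (omega) of the exponential inter-subject
    random effect (reported as CV% = 100*omega); ``fixed`` lists fixed
    effects that are never estimated (the absorption rate constant of the
    THEORY model).
    """

    model_id: str  # {MM, THEORY}
    fixed_effects: dict[str, float]
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    random_effects: dict[str, float] = field(default_factory=dict)
    residual: ResidualModel = field(default_factory=lambda: ResidualModel("proportional", 0.2))
    time_factor_enabled: bool = False
    fixed: tuple[str, ...] = ()
    partition: PartitionConstants = DEFAULT_PARTITION
    hct_as_fraction: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.model_id not in ("MM", "THEORY", "LINEAR"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.model_id == "THEORY" and "ka" not in self.fixed_effects:
            raise ValueError("THEORY model requires an absorption rate constant ka")
        for p, tv in self.fixed_effects.items():
            if not tv > 0:
                raise ValueError(f"typical value of {p} must be positive")
        for p, om in self.random_effects.items():
            if om < 0:
                raise ValueError(f"omega for {p} must be nonnegative")

    # -- convenience ------------------------------------------------------
    @property
    def eta_names(self) -> list[str]:
        return list(self.random_effects)

    @property
    def n_eta(self) -> int:
        return len(self.random_effects)

    @property
    def dv_column(self) -> str:
        return "daily_dose" if self.model_id == "MM" else "c0"

    def effects_on(self, parameter: str) -> list[CovariateEffect]:
        return [e for e in self.covariate_effects if e.parameter == parameter]

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + [effect])

    def without_effect(self, label: str) -> "ModelSpec":
        kept = [e for e in self.covariate_effects if e.label != label]
        return replace(self, covariate_effects=kept)

    def copy(self) -> "ModelSpec":
        return replace(
            self,
            fixed_effects=dict(self.fixed_effects),
            covariate_effects=list(self.covariate_effects),
            random_effects=dict(self.random_effects),
        )


def typical_params(spec: ModelSpec, data: FlatData) -> dict[str, np.ndarray]:
    """Per-observation covariate-adjusted typical parameter values (eta = 0).

    Computed once per parameter vector; the inner random-effects search
    only rescales these by exp(eta).
    """
    params: dict[str, np.ndarray] = {}
    for p, tv in spec.fixed_effects.items():
        base = np.full(data.n_obs, float(tv))
        mult = np.ones(data.n_obs)
        for eff in spec.effects_on(p):
            kind, val = covariate_factor(eff, data.col(eff.covariate))
            if kind == "add":
                base = base + val
            else:
                mult = mult * val
        params[p] = base * mult
    return params


def _individual_params(
    spec: ModelSpec,
    data: FlatData,
    eta: np.ndarray | None,
    typ: dict[str, np.ndarray] | None = None,
):
    """Per-observation realized structural parameters.

    ``eta`` is (n_subjects, n_eta) in the order of ``spec.eta_names``.
    """
    if typ is None:
        typ = typical_params(spec, data)
    if eta is None or not spec.n_eta:
        return dict(typ)
    eta_obs = data.expand(np.asarray(eta, dtype=float).reshape(data.n_subjects, -1))
    params = dict(typ)
    for j, name in enumerate(spec.eta_names):
        params[name] = typ[name] * np.exp(eta_obs[:, j])
    return params


def predict(
    spec: ModelSpec,
    data: FlatData,
    eta: np.ndarray | None = None,
    typ: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Vectorized prediction of the dependent variable for every row.

    MM: predicted daily dose from the observed trough.
    THEORY: predicted whole-blood trough from the administered daily dose
    (split q12h, trough at 12 h after dose).
    LINEAR: additive random-intercept regression on postoperative day --
    an eta-linear Gaussian model whose marginal likelihood has a closed
    form, used to validate the estimation machinery.
    """
    if spec.model_id == "LINEAR":
        f = spec.fixed_effects["intercept"] + spec.fixed_effects["slope"] * data.col("pod")
        if eta is not None and spec.n_eta:
            eta_obs = data.expand(np.asarray(eta, dtype=float).reshape(data.n_subjects, -1))
            f = f + eta_obs[:, 0]
        return f
    p = _individual_params(spec, data, eta, typ)
    if spec.model_id == "MM":
        return mm_dose_pred(
            p["vm"], p["km"], data.col("c0"), data.col("pod"), spec.time_factor_enabled
        )
    cp = ss_trough_plasma(
        p["cl"], p["v"], spec.fixed_effects["ka"], data.col("daily_dose") / 2.0
    )
    hct = data.col("hct")
    if spec.hct_as_fraction:
        hct = hct / 100.0
    return plasma_to_blood(cp, hct, spec.partition)


def simulate_dv(
    spec: ModelSpec,
    data: FlatData,
    rng: np.random.Generator,
    n_replicates: int = 1,
    return_eta: bool = False,
):
    """Simulate dependent-variable replicates on the dataset's own design.

    Draws fresh subject-level etas and observation-level residuals per
    replicate; regressors (trough for MM, dose for THEORY) and covariates
    are taken from the dataset as-is.  Returns (n_replicates, n_obs).
    """
    omega = np.array([spec.random_effects[k] for k in spec.eta_names])
    out = np.empty((n_replicates, data.n_obs))
    etas = np.empty((n_replicates, data.n_subjects, spec.n_eta))
    for r in range(n_replicates):
        eta = rng.standard_normal((data.n_subjects, spec.n_eta)) * omega
        f = predict(spec, data, eta)
        res = spec.residual
        if res.form == "additive":
            y = f + rng.standard_normal(data.n_obs) * res.sigma1
        elif res.form == "proportional":
            y = f * (1.0 + rng.standard_normal(data.n_obs) * res.sigma1)
        else:
            y = (
                f * (1.0 + rng.standard_normal(data.n_obs) * res.sigma1)
                + rng.standard_normal(data.n_obs) * res.sigma2
            )
        out[r] = y
        etas[r] = eta
    if return_eta:
        return out, etas
    return out


# ---------------------------------------------------------------------------
# shipped presets (published estimates, used as simulation ground truth)


def mm_base() -> ModelSpec:
    return ModelSpec(
        model_id="MM",
        fixed_effects={"vm": 6.1, "km": 6.19},
        random_effects={"km": 0.748},
        residual=ResidualModel("combined", 0.29, 0.48),
        time_factor_enabled=False,
        name="mm_base",
    )


def mm_final() -> ModelSpec:
    return ModelSpec(
        model_id="MM",
        fixed_effects={"vm": 6.62, "km": 6.46},
        covariate_effects=[
            CovariateEffect("km", "pod", "power", 0.277, reference=15.0),
            CovariateEffect("km", "hct", "power", 1.16, reference=31.0),
            CovariateEffect("km", "tbil", "power", 0.286, reference=58.25),
            CovariateEffect("km", "cyp3a5_carrier", "scale", -0.365),
            CovariateEffect("km", "taf", "scale", 2.15),
        ],
        random_effects={"km": 0.653},
        residual=ResidualModel("combined", 0.204, 0.568),
        time_factor_enabled=True,
        name="mm_final",
    )


def theory_base() -> ModelSpec:
    return ModelSpec(
        model_id="THEORY",
        fixed_effects={"cl": 456.0, "v": 10700.0, "ka": 4.48},
        random_effects={"cl": 0.422, "v": 0.644},
        residual=ResidualModel("proportional", 0.143),
        fixed=("ka",),
        name="theory_base",
    )


def theory_final() -> ModelSpec:
    return ModelSpec(
        model_id="THEORY",
        fixed_effects={"cl": 234.0, "v": 11000.0, "ka": 4.48},
        covariate_effects=[
            CovariateEffect("cl", "ast", "power", -0.216, reference=45.0),
            CovariateEffect("cl", "daily_dose", "saturable_emax", 3.51, theta2=2.44),
            CovariateEffect("cl", "cyp3a5_carrier", "scale", 0.168),
            CovariateEffect("cl", "taf", "scale", -0.575),
            CovariateEffect("v", "pod", "exponential", 0.887, reference=15.0),
        ],
        random_effects={"cl": 0.297, "v": 0.592},
        residual=ResidualModel("proportional", 0.308),
        fixed=("ka",),
        name="theory_final",
    )


_PRESETS = {
    "mm_base": mm_base,
    "mm_final": mm_final,
    "theory_base": theory_base,
    "theory_final": theory_final,
}


def preset(name: str) -> ModelSpec:
    """Look up a shipped model preset by name."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
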