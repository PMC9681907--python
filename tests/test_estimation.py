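"""Estimation-engine correctness: conditional modes, objective oracles,
shrinkage and the stepwise search on constructed fixtures."""

import numpy as np
import pytest
from scipy import integrate

import tacropk as tk
from tacropk.estimation import _joint_objective, foce_ofv, conditional_eta_mode
from conftest import exact_linear_m2ll, linear_dataset, make_linear_spec


def small_mm_fixture(n_subjects=5, n_obs=3, seed=5):
    """Tiny MM dataset with known per-row regressors."""
    rng = np.random.default_rng(seed)
    spec = tk.mm_base()
    subjects = []
    for i in range(n_subjects):
        eta = rng.normal(0, spec.random_effects["km"])
        rows = []
        for j in range(n_obs):
            c0 = float(rng.uniform(3, 15))
            f = float(tk.mm_dose_pred(6.1, 6.19 * np.exp(eta), c0))
            dd = f * (1 + rng.normal(0, 0.29)) + rng.normal(0, 0.48)
            rows.append(tk.ObservationRow(pod=float(j + 3), daily_dose=max(dd, 0.1), c0=c0))
        subjects.append(tk.SubjectRecord(subject_id=f"M{i}", rows=rows))
    return tk.FlatData(subjects), spec


class TestConditionalMode:
    def test_zero_residual_data_gives_zero_mode(self):
        # additive error: with every residual zero at eta=0 the penalized
        # objective is minimized exactly at zero (heteroscedastic error
        # models shift the mode through the log-variance term)
        spec = tk.mm_base()
        spec.residual = tk.ResidualModel("additive", 0.48)
        rows = []
        for c0 in (4.0, 8.0, 12.0):
            rows.append(
                tk.ObservationRow(pod=5.0, daily_dose=float(tk.mm_dose_pred(6.1, 6.19, c0)), c0=c0)
            )
        mode, hess = conditional_eta_mode(tk.SubjectRecord(subject_id="S", rows=rows), spec)
        assert mode == pytest.approx(0.0, abs=1e-6)
        assert hess[0, 0] > 0

    def test_linear_model_mode_matches_ridge_solution(self):
        data, spec = linear_dataset(n_subjects=1, n_obs=4, seed=3)
        subj = tk.SubjectRecord(
            subject_id="L0",
            rows=[
                tk.ObservationRow(pod=p, daily_dose=1.0, c0=y)
                for p, y in zip(data.col("pod"), data.col("c0"))
            ],
        )
        mode, _ = conditional_eta_mode(subj, spec)
        resid = data.col("c0") - (
            spec.fixed_effects["intercept"] + spec.fixed_effects["slope"] * data.col("pod")
        )
        om2, s2 = spec.random_effects["intercept"] ** 2, spec.residual.sigma1 ** 2
        ridge = om2 * resid.sum() / (s2 + len(resid) * om2)
        assert mode[0] == pytest.approx(ridge, abs=1e-7)

    def test_mm_mode_matches_dense_grid(self):
        data, spec = small_mm_fixture(n_subjects=1)
        y = data.col("daily_dose")
        omega = np.array([spec.random_effects["km"]])
        q = _joint_objective(spec, data, y, omega)
        grid = np.linspace(-4, 4, 200001)[:, None]
        vals = np.array([q(np.array([[g]]))[0] for g in grid[:, 0][::100]])
        coarse_best = grid[::100][np.argmin(vals), 0]
        fine = np.linspace(coarse_best - 0.1, coarse_best + 0.1, 20001)
        vals_fine = np.array([q(np.array([[g]]))[0] for g in fine])
        grid_mode = fine[np.argmin(vals_fine)]
        subj_rows = [
            tk.ObservationRow(pod=p, daily_dose=d, c0=c)
            for p, d, c in zip(data.col("pod"), data.col("daily_dose"), data.col("c0"))
        ]
        mode, _ = conditional_eta_mode(tk.SubjectRecord(subject_id="S", rows=subj_rows), spec)
        assert mode[0] == pytest.approx(grid_mode, abs=1e-4)


class TestObjectiveOracles:
    @pytest.mark.parametrize("method", ["foce", "laplace", "agq"])
    def test_linear_gaussian_exactness(self, method):
        """On an eta-linear Gaussian model every conditional-mode
        objective equals the closed-form marginal -2 log likelihood."""
        data, spec = linear_dataset(n_subjects=12, n_obs=4, seed=1)
        exact = exact_linear_m2ll(data, spec)
        approx = foce_ofv(data, spec, method=method)
        assert approx == pytest.approx(exact, abs=1e-6)

    def test_linear_gaussian_exact_off_truth_too(self):
        data, _ = linear_dataset(n_subjects=8, n_obs=3, seed=2)
        spec = make_linear_spec(intercept=11.0, slope=0.3, omega=0.8, sigma=1.1)
        assert foce_ofv(data, spec) == pytest.approx(exact_linear_m2ll(data, spec), abs=1e-6)

    def test_nonlinear_quadrature_oracle(self):
        """FOCE within 0.5% of numerically integrated -2 log marginal
        likelihood on a 5-subject MM fixture."""
        data, spec = small_mm_fixture(n_subjects=5)
        y = data.col("daily_dose")
        omega = np.array([spec.random_effects["km"]])
        q = _joint_objective(spec, data, y, omega)
        total = 0.0
        for i in range(data.n_subjects):
            def integrand(e, i=i):
                eta = np.zeros((data.n_subjects, 1))
                eta[i, 0] = e
                return np.exp(-0.5 * q(eta)[i])
            val, _ = integrate.quad(integrand, -6, 6, epsabs=1e-13, epsrel=1e-11, limit=200)
            n_i = data.counts[i]
            total += -2 * np.log(val) + n_i * np.log(2 * np.pi) + np.log(2 * np.pi) \
                + 2 * np.log(omega[0])
        # the quadrature objective used for fitting is near-exact; the
        # linearized forms carry the known FOCE/Laplace approximation
        # error at 75% inter-subject variability
        assert foce_ofv(data, spec, method="agq") == pytest.approx(total, rel=5e-3)
        assert foce_ofv(data, spec, method="foce") == pytest.approx(total, rel=2e-2)
        assert foce_ofv(data, spec, method="laplace") == pytest.approx(total, rel=2e-2)

    def test_omega_to_zero_is_pooled_els(self):
        data, spec = small_mm_fixture(n_subjects=4)
        tiny = spec.copy()
        tiny.random_effects["km"] = 1e-10
        f = tk.predict(spec, data, np.zeros((data.n_subjects, 1)))
        v = tk.residual_variance(f, spec.residual)
        y = data.col("daily_dose")
        pooled = float(np.sum(np.log(v) + (y - f) ** 2 / v) + data.n_obs * np.log(2 * np.pi))
        assert foce_ofv(data, tiny) == pytest.approx(pooled, rel=1e-6)


class TestFitModel:
    def test_fit_improves_ofv_and_reports_rse(self):
        data, spec = small_mm_fixture(n_subjects=30, n_obs=5, seed=11)
        start = spec.copy()
        start.fixed_effects.update({"vm": 8.0, "km": 4.0})
        fit = tk.fit_model(data, start, compute_rse=True, maxiter=150)
        assert fit.ofv <= foce_ofv(data, start) + 1e-9
        assert set(fit.rse_percent) == set(fit.param_names)
        assert np.isfinite(fit.ofv)

    def test_single_subject_omega_free_reduces_to_nls(self):
        # troughs spanning the saturating range so Vm and Km separate
        rng = np.random.default_rng(13)
        rows = []
        for j, c0 in enumerate(np.linspace(2, 60, 12)):
            f = float(tk.mm_dose_pred(6.1, 6.19, c0))
            rows.append(
                tk.ObservationRow(pod=float(j + 3), daily_dose=f + float(rng.normal(0, 0.3)),
                                  c0=float(c0))
            )
        data = tk.FlatData([tk.SubjectRecord(subject_id="S", rows=rows)])
        nospread = tk.ModelSpec(
            model_id="MM",
            fixed_effects={"vm": 6.1, "km": 6.19},
            random_effects={},
            residual=tk.ResidualModel("additive", 0.4),
        )
        fit = tk.fit_model(data, nospread, compute_rse=False, maxiter=300)
        # additive-error, no-eta fit minimizes the residual sum of squares
        from scipy.optimize import minimize

        y, c0 = data.col("daily_dose"), data.col("c0")

        def rss(p):
            return float(np.sum((y - tk.mm_dose_pred(np.exp(p[0]), np.exp(p[1]), c0)) ** 2))

        ref = minimize(rss, np.log([6.0, 6.0]), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14})
        assert rss(np.log([fit.estimates["tv_vm"], fit.estimates["tv_km"]])) <= ref.fun * (1 + 1e-5)
        assert fit.estimates["tv_vm"] == pytest.approx(np.exp(ref.x[0]), rel=1e-2)
        assert fit.estimates["tv_km"] == pytest.approx(np.exp(ref.x[1]), rel=2e-2)

    def test_mm_basin_robustness_to_perturbed_inits(self):
        subjects, _ = tk.generate_dataset(
            tk.CohortSpec(n_subjects=120), tk.TruthModel(spec=tk.mm_final()), seed=77
        )
        data = tk.FlatData(subjects)
        fit_truth_init = tk.fit_model(data, tk.mm_final(), compute_rse=False, maxiter=400)
        pert = tk.mm_final()
        pert.fixed_effects.update({"vm": 6.62 * 1.5, "km": 6.46 * 0.5})
        fit_pert_init = tk.fit_model(data, pert, compute_rse=False, maxiter=400)
        assert fit_pert_init.ofv == pytest.approx(fit_truth_init.ofv, abs=0.1)

    def test_nesting_never_raises_optimal_ofv(self, mm_cohort):
        subjects, _ = mm_cohort
        data = tk.FlatData(subjects)
        base = tk.mm_base()
        fit_base = tk.fit_model(data, base, compute_rse=False, maxiter=200)
        richer = base.with_effect(tk.CovariateEffect("km", "hct", "power", 0.1, reference=31.0))
        fit_rich = tk.fit_model(data, richer, compute_rse=False, maxiter=200)
        assert fit_rich.ofv <= fit_base.ofv + 0.05


class TestShrinkage:
    def test_all_zero_modes_give_full_shrinkage(self, mm_data):
        spec = tk.mm_final()
        modes = np.zeros((mm_data.n_subjects, 1))
        eta_shr, _ = tk.shrinkage_stats(spec, mm_data, modes)
        assert eta_shr["km"] == pytest.approx(100.0)

    def test_rich_simulated_data_shrinks_little(self):
        subjects, _ = tk.generate_dataset(
            tk.CohortSpec(n_subjects=150), tk.TruthModel(spec=tk.mm_final()), seed=55
        )
        data = tk.FlatData(subjects)
        ofv, modes = foce_ofv(data, tk.mm_final(), return_modes=True)
        eta_shr, eps_shr = tk.shrinkage_stats(tk.mm_final(), data, modes)
        assert eta_shr["km"] < 20.0
        assert abs(eps_shr) < 20.0


class TestStepwise:
    def _planted_truth(self):
        return tk.ModelSpec(
            model_id="MM",
            fixed_effects={"vm": 6.62, "km": 6.46},
            covariate_effects=[tk.CovariateEffect("km", "hct", "power", 1.16, reference=31.0)],
            random_effects={"km": 0.55},
            residual=tk.ResidualModel("combined", 0.2, 0.5),
        )

    def test_no_qualifying_candidate_returns_base(self, mm_cohort):
        subjects, _ = mm_cohort
        data = tk.FlatData(subjects)
        base = tk.mm_base()
        # albumin carries no true effect in the generator truth
        final, log = tk.stepwise_search(
            data, base, [("km", "alb", "power")], maxiter=120
        )
        included = [r for r in log if r.decision == "included"]
        if not included:
            assert final.covariate_effects == base.covariate_effects

    def test_planted_covariate_recovered_with_correct_sign(self):
        truth = self._planted_truth()
        subjects, _ = tk.generate_dataset(
            tk.CohortSpec(n_subjects=150), tk.TruthModel(spec=truth), seed=303
        )
        data = tk.FlatData(subjects)
        base = truth.copy()
        base.covariate_effects = []
        final, log = tk.stepwise_search(
            data, base,
            [("km", "hct", "power"), ("km", "alb", "power")],
            maxiter=150,
        )
        labels = [e.label for e in final.covariate_effects]
        assert "km~hct:power" in labels
        theta = [e.theta for e in final.covariate_effects if e.label == "km~hct:power"][0]
        assert theta > 0  # correct direction
        step = [r for r in log if r.decision == "included" and "hct" in r.candidate][0]
        assert step.delta_ofv >= 3.84

    def test_collinear_candidates_include_only_one(self):
        truth = self._planted_truth()
        subjects, _ = tk.generate_dataset(
            tk.CohortSpec(n_subjects=120), tk.TruthModel(spec=truth), seed=404
        )
        # construct a collinear twin of hematocrit
        for s in subjects:
            for r in s.rows:
                r.alb = r.hct * 1.2
        data = tk.FlatData(subjects)
        base = truth.copy()
        base.covariate_effects = []
        final, _ = tk.stepwise_search(
            data, base,
            [("km", "hct", "power"), ("km", "alb", "power")],
            maxiter=150,
        )
        labels = [e.label for e in final.covariate_effects]
        assert len([l for l in labels if l in ("km~hct:power", "km~alb:power")]) == 1
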