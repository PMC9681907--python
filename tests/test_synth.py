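"""Synthetic cohort generator: covariate marginals, genotype frequencies,
renal-function formula, titration dynamics and reproducibility."""

import numpy as np
import pytest

import tacropk as tk
from tacropk.synth import cockcroft_gault, hwe_test, sample_covariates, sample_genotypes


class TestCovariateSampling:
    @pytest.fixture(scope="class")
    def big_sample(self):
        cohort = tk.CohortSpec(n_subjects=10_000)
        subjects = sample_covariates(cohort, seed=9)
        return cohort, subjects

    def test_age_matches_cohort_summary(self, big_sample):
        _, subjects = big_sample
        ages = np.array([s.age for s in subjects])
        assert abs(ages.mean() - 50.68) < 1.0
        assert ages.min() >= 18.0 and ages.max() <= 74.0

    @pytest.mark.parametrize(
        "attr,mean,sd",
        [
            ("age", 50.68, 9.71),
            ("weight", 64.54, 11.85),
            ("height", 1.69, 0.06),
            ("ffm", 50.27, 8.50),
            ("graft_weight", 1310.35, 207.42),
        ],
    )
    def test_demographic_moments_within_5_percent(self, big_sample, attr, mean, sd):
        _, subjects = big_sample
        vals = np.array([getattr(s, attr) for s in subjects])
        assert abs(vals.mean() - mean) / mean < 0.05
        assert abs(vals.std() - sd) / sd < 0.05

    @pytest.mark.parametrize(
        "key,mean,sd,skewed",
        [("hct", 31.78, 4.98, False), ("alb", 37.24, 4.05, False),
         ("ast", 83.54, 143.15, True), ("alt", 138.99, 183.99, True),
         ("tbil", 88.32, 90.11, True), ("scr", 62.15, 28.47, False)],
    )
    def test_lab_moments_match(self, big_sample, key, mean, sd, skewed):
        # the sample SD of the heavy-tailed labs fluctuates by >10% even
        # at n=10^4, so their sampled spread gets a wider band while the
        # analytic moments of the sampler are checked exactly below
        _, subjects = big_sample
        vals = np.array([getattr(s, "_baseline")[key] for s in subjects])
        assert abs(vals.mean() - mean) / mean < 0.05
        assert abs(vals.std() - sd) / sd < (0.25 if skewed else 0.05)

    @pytest.mark.parametrize(
        "key", ["age", "weight", "hct", "alb", "ast", "alt", "tbil", "scr"]
    )
    def test_sampler_analytic_moments_exact(self, key):
        from scipy import stats as ss
        from tacropk.synth import (
            _DEFAULT_COVARIATES, _truncnorm_params, _trunc_lognorm_params,
            _trunc_lognorm_moments,
        )

        kind, mean, sd, lo, hi = _DEFAULT_COVARIATES[key]
        if kind == "normal":
            mu, sig = _truncnorm_params(mean, sd, lo, hi)
            a, b = (lo - mu) / sig, (hi - mu) / sig
            m, v = ss.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
            s = np.sqrt(v)
        else:
            mu, sig = _trunc_lognorm_params(mean, sd, lo, hi)
            m, s = _trunc_lognorm_moments(mu, sig, lo, hi)
        assert m == pytest.approx(mean, rel=5e-3)
        assert s == pytest.approx(sd, rel=5e-3)

    def test_skewed_labs_are_right_skewed(self, big_sample):
        _, subjects = big_sample
        ast = np.array([s._baseline["ast"] for s in subjects])
        assert np.median(ast) < ast.mean() * 0.75


class TestCockcroftGault:
    def test_hand_value_male(self):
        assert cockcroft_gault(51.0, 64.0, 57.0, False) == pytest.approx(122.2, abs=0.1)

    def test_female_multiplier(self):
        m = cockcroft_gault(51.0, 64.0, 57.0, False)
        f = cockcroft_gault(51.0, 64.0, 57.0, True)
        assert f == pytest.approx(0.85 * m)

    def test_clcr_in_dataset_is_derived_not_sampled(self, mm_cohort):
        subjects, _ = mm_cohort
        for s in subjects[:10]:
            for r in s.rows:
                expected = cockcroft_gault(s.age, s.weight, r.scr, s.sex == "female")
                assert r.clcr == pytest.approx(float(expected), rel=1e-9)


class TestGenotypes:
    def test_frequencies_converge(self):
        cohort = tk.CohortSpec(n_subjects=10_000)
        subjects = sample_covariates(cohort, seed=1)
        sample_genotypes(cohort, subjects, seed=2)
        counts = np.bincount([s.genotype_cyp3a5_recipient for s in subjects], minlength=3)
        # expected genotype fractions for the recipient CYP3A5 locus
        expected = np.array([93, 71, 12]) / 176
        from scipy import stats

        chi2 = np.sum((counts - expected * 10_000) ** 2 / (expected * 10_000))
        assert stats.chi2.sf(chi2, df=2) > 0.01
        assert abs(counts[0] / 10_000 - 0.5284) < 0.02

    def test_hwe_chi2_zero_at_exact_proportions(self):
        # 0.25/0.5/0.25 are exact Hardy-Weinberg proportions for p=0.5
        chi2, p = hwe_test((25, 50, 25))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hwe_rejects_missing_heterozygotes(self):
        chi2, p = hwe_test((50, 0, 50))
        assert chi2 == pytest.approx(100.0)
        assert p < 0.001


class TestTdmCourse:
    def test_noiseless_titration_reaches_target_window(self):
        # typical-covariate subject (cohort medians, non-expresser, no
        # antifungal): the titration map contracts into the window
        s = tk.SubjectRecord(subject_id="typ")
        s._baseline = {"hct": 31.3, "alb": 37.0, "alt": 69.0, "ast": 45.0,
                       "tbil": 58.25, "scr": 57.0}
        s._taf = 0
        truth = tk.TruthModel(spec=tk.mm_final(), assay_cv=0.0)
        rows = tk.simulate_tdm_course(s, truth, seed=7, eta=np.zeros(1), residual_noise=False)
        assert len(rows) >= 2
        in_window = [8.0 <= r.c0 <= 12.0 for r in rows]
        # the proportional rule overshoots once (the dose->trough map is
        # superlinear near saturation) and settles on the next correction
        assert any(in_window[:5])
        assert in_window[-1]  # and stays there

    def test_noiseless_rows_satisfy_mm_relation_exactly(self):
        cohort = tk.CohortSpec(n_subjects=5)
        subjects = sample_covariates(cohort, seed=32)
        sample_genotypes(cohort, subjects, seed=32)
        truth = tk.TruthModel(spec=tk.mm_final(), assay_cv=0.0)
        spec = truth.spec
        for i, s in enumerate(subjects):
            s._taf = 0
            rows = tk.simulate_tdm_course(s, truth, seed=i, eta=np.zeros(1), residual_noise=False)
            for r in rows:
                covs = {
                    "pod": r.pod, "hct": r.hct, "tbil": r.tbil,
                    "cyp3a5_carrier": float(s.genotype_cyp3a5_recipient > 0), "taf": 0.0,
                }
                km = float(tk.individual_param(spec.fixed_effects["km"],
                                               spec.effects_on("km"), covs, 0.0))
                dd = float(tk.mm_dose_pred(spec.fixed_effects["vm"], km, r.c0, r.pod, True))
                assert r.daily_dose == pytest.approx(dd, rel=1e-9)

    def test_generated_doses_match_cohort_summary(self):
        subjects, _ = tk.generate_dataset(
            tk.CohortSpec(n_subjects=176), tk.TruthModel(spec=tk.mm_final()), seed=3
        )
        dd = np.array([r.daily_dose for s in subjects for r in s.rows])
        assert abs(dd.mean() - 2.73) < 0.5

    def test_median_visits_and_pod_window(self, mm_cohort):
        subjects, _ = mm_cohort
        counts = [len(s.rows) for s in subjects]
        assert 4 <= np.median(counts) <= 6
        pods = [r.pod for s in subjects for r in s.rows]
        assert min(pods) >= 2 and max(pods) <= 72


class TestGenerateDataset:
    def test_reproducible_from_seed(self):
        a, gta = tk.generate_dataset(tk.CohortSpec(n_subjects=20), tk.TruthModel(spec=tk.mm_final()), seed=12)
        b, gtb = tk.generate_dataset(tk.CohortSpec(n_subjects=20), tk.TruthModel(spec=tk.mm_final()), seed=12)
        fa = tk.datamodel.subjects_to_frame(a)
        fb = tk.datamodel.subjects_to_frame(b)
        assert fa.equals(fb)
        assert gta["eta"] == gtb["eta"]

    def test_passes_validation_with_no_hard_errors(self, mm_cohort):
        subjects, _ = mm_cohort
        report = tk.validate_dataset(subjects)
        hard = [
            f for f in report.flags
            if f.code in ("nonpositive_c0", "nonpositive_dose", "not_steady_state",
                          "implausible_covariate", "age")
        ]
        assert hard == []

    def test_theory_truth_blood_values_invertible(self, theory_cohort):
        subjects, _ = theory_cohort
        for s in subjects:
            for r in s.rows:
                assert r.c0 > 0
                cp = float(tk.blood_to_plasma(r.c0, r.hct / 100.0))
                assert 0 < cp < r.c0

    def test_ground_truth_sidecar_covers_all_subjects(self, mm_cohort):
        subjects, gt = mm_cohort
        assert set(gt["eta"]) == {s.subject_id for s in subjects}
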