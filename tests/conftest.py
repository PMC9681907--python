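import numpy as np
import pytest

import tacropk as tk


@pytest.fixture(scope="session")
def mm_cohort():
    """Small MM-truth cohort shared by read-only tests."""
    subjects, gt = tk.generate_dataset(
        tk.CohortSpec(n_subjects=60), tk.TruthModel(spec=tk.mm_final()), seed=101
    )
    return subjects, gt


@pytest.fixture(scope="session")
def mm_data(mm_cohort):
    subjects, _ = mm_cohort
    return tk.FlatData(subjects)


@pytest.fixture(scope="session")
def theory_cohort():
    subjects, gt = tk.generate_dataset(
        tk.CohortSpec(n_subjects=40), tk.TruthModel(spec=tk.theory_base()), seed=202
    )
    return subjects, gt


def make_linear_spec(intercept=10.0, slope=0.5, omega=1.2, sigma=0.7):
    """Random-intercept regression: eta-linear, Gaussian, closed-form
    marginal likelihood."""
    return tk.ModelSpec(
        model_id="LINEAR",
        fixed_effects={"intercept": intercept, "slope": slope},
        random_effects={"intercept": omega},
        residual=tk.ResidualModel("additive", sigma),
    )


def linear_dataset(n_subjects=12, n_obs=4, seed=0):
    """Subjects whose 'c0' column holds draws from the linear model."""
    rng = np.random.default_rng(seed)
    spec = make_linear_spec()
    subjects = []
    for i in range(n_subjects):
        eta = rng.normal(0, spec.random_effects["intercept"])
        rows = []
        for j in range(n_obs):
            pod = float(j + 1)
            y = (
                spec.fixed_effects["intercept"]
                + spec.fixed_effects["slope"] * pod
                + eta
                + rng.normal(0, spec.residual.sigma1)
            )
            rows.append(tk.ObservationRow(pod=pod, daily_dose=1.0, c0=y))
        subjects.append(tk.SubjectRecord(subject_id=f"L{i}", rows=rows))
    return tk.FlatData(subjects), spec


def exact_linear_m2ll(data, spec):
    """Closed-form multivariate-normal -2 log likelihood of the linear
    random-intercept model (the estimation oracle)."""
    from scipy import stats

    om2 = spec.random_effects["intercept"] ** 2
    s2 = spec.residual.sigma1 ** 2
    total = 0.0
    y = data.col("c0")
    for i in range(data.n_subjects):
        sl = slice(data.starts[i], data.starts[i] + data.counts[i])
        pod = data.col("pod")[sl]
        mean = spec.fixed_effects["intercept"] + spec.fixed_effects["slope"] * pod
        n = len(pod)
        cov = om2 * np.ones((n, n)) + s2 * np.eye(n)
        total += -2.0 * stats.multivariate_normal.logpdf(y[sl], mean=mean, cov=cov)
    return total
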