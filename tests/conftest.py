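import pytest

import roadzone as rz


@pytest.fixture(scope="session")
def study_records():
    """One study-condition dataset: 280 realized detector-nights simulated
    with the published all-species coefficients."""
    design = rz.study_design(seed=11)
    cov = rz.sample_covariates(design, seed=12)
    rec = rz.simulate_counts(design, cov, rz.STUDY_COMBINED_COEFS, seed=13)
    return design, cov, rec


@pytest.fixture(scope="session")
def small_fit():
    """A quick converged fit on a reduced design, shared by tests that only
    need a fitted model object."""
    design = rz.apply_missingness(
        rz.build_design(6, [10, 100, 500, 2000], 2), {}, seed=0)
    cov = rz.sample_covariates(design, seed=1)
    rec = rz.simulate_counts(
        design, cov,
        rz.CoefficientSet(2.0, 0.4, -0.15, 0.0, 0.05, 0.3), seed=2)
    model = rz.HierarchicalPoissonRegression(
        chains=3, iterations=4000, burn_in=1000, thinning=2,
        random_state=3).fit(rec)
    return rec, model
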