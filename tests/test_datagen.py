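"""Generator tests: beta marginals, copula calibration, quota sampling."""

import numpy as np
import pytest
from scipy import stats

from cpgset import (
    BetaMarginalSpec,
    CorrelationTarget,
    DiseaseModelSpec,
    ScenarioSpec,
    beta_params_from_mean,
    calibrate_copula,
    outcome_probability,
    sample_case_control,
    sample_correlated_beta,
)
from cpgset.datagen import (
    InfeasibleCorrelationError,
    QuotaExhaustedError,
    _induced_pearson,
    nearest_psd_correlation,
)


@pytest.mark.parametrize(
    "mean,precision,expected",
    [(0.5, 2.0, (1.0, 1.0)), (0.6, 10.0, (6.0, 4.0)), (0.2, 10.0, (2.0, 8.0))],
)
def test_beta_params_from_mean(mean, precision, expected):
    assert beta_params_from_mean(mean, precision) == pytest.approx(expected)


@pytest.mark.parametrize("mean,precision", [(0.0, 10), (1.0, 10), (-0.1, 10), (0.5, 0.0), (0.5, -3)])
def test_beta_params_rejects_invalid(mean, precision):
    with pytest.raises(ValueError):
        beta_params_from_mean(mean, precision)


def test_marginal_monte_carlo_mean():
    """Sample mean of 1e5 draws within 3 standard errors of the target mean."""
    m = BetaMarginalSpec(0.2, 10.0)
    a, b = m.shapes
    draws = stats.beta.rvs(a, b, size=100_000, random_state=7)
    se = m.sd / np.sqrt(draws.size)
    assert abs(draws.mean() - 0.2) < 3 * se


def test_calibrate_zero_target_gives_identity():
    marginals = [BetaMarginalSpec(0.4), BetaMarginalSpec(0.7)]
    spec = calibrate_copula(marginals, CorrelationTarget.exchangeable(0.0, 2))
    np.testing.assert_allclose(spec.latent_correlation, np.eye(2), atol=1e-12)


def test_calibrate_comonotone_identical_marginals():
    """Identical marginals with target r = 1 map to latent rho = 1."""
    marginals = [BetaMarginalSpec(0.6)] * 2
    spec = calibrate_copula(marginals, CorrelationTarget.exchangeable(1.0, 2))
    assert spec.latent_correlation[0, 1] == pytest.approx(1.0, abs=1e-6)


def test_calibrated_copula_reproduces_target_correlation():
    """Monte Carlo oracle: resampling the calibrated spec recovers r = 0.8."""
    marginals = [BetaMarginalSpec(0.6, 10.0)] * 3
    spec = calibrate_copula(marginals, CorrelationTarget.exchangeable(0.8, 3))
    mat = sample_correlated_beta(spec, 100_000, seed=11)
    r = np.corrcoef(mat.values.T)[np.triu_indices(3, 1)]
    assert np.all(r > 0.78) and np.all(r < 0.82)


def test_infeasible_correlation_raises():
    """Opposite-skew marginals cannot reach near-perfect Pearson correlation."""
    marginals = [BetaMarginalSpec(0.05, 50.0), BetaMarginalSpec(0.95, 50.0)]
    upper = _induced_pearson(marginals[0], marginals[1], 1.0)
    assert upper < 0.995  # the Frechet bound really binds here
    with pytest.raises(InfeasibleCorrelationError):
        calibrate_copula(marginals, CorrelationTarget.exchangeable(0.999, 2))


def test_marginal_goodness_of_fit_single_column():
    """p = 1 sampling matches the closed-form beta law (KS check at 1e5)."""
    m = BetaMarginalSpec(0.3, 10.0)
    spec = calibrate_copula([m], CorrelationTarget(np.eye(1)))
    mat = sample_correlated_beta(spec, 100_000, seed=5)
    a, b = m.shapes
    ks = stats.kstest(mat.values[:, 0], stats.beta(a, b).cdf)
    assert ks.pvalue > 0.01


def test_sampling_is_deterministic(exchangeable_copula):
    a = sample_correlated_beta(exchangeable_copula, 500, seed=99)
    b = sample_correlated_beta(exchangeable_copula, 500, seed=99)
    np.testing.assert_array_equal(a.values, b.values)


def test_sampled_values_in_open_interval(exchangeable_copula):
    mat = sample_correlated_beta(exchangeable_copula, 2000, seed=3)
    assert mat.values.min() > 0.0 and mat.values.max() < 1.0


def test_exact_ppf_path_agrees_with_table(exchangeable_copula):
    interp = sample_correlated_beta(exchangeable_copula, 2000, seed=8)
    exact = sample_correlated_beta(exchangeable_copula, 2000, seed=8, exact_ppf=True)
    np.testing.assert_allclose(interp.values, exact.values, atol=1e-5)


def test_nearest_psd_projection():
    m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    fixed = nearest_psd_correlation(m)
    assert np.linalg.eigvalsh(fixed).min() >= 0
    np.testing.assert_allclose(np.diag(fixed), 1.0)


def test_outcome_probability_null_model():
    disease = DiseaseModelSpec(intercept=0.0)
    assert outcome_probability(np.array([0.2, 0.9]), disease) == pytest.approx(0.5)


def test_outcome_probability_single_effect():
    """Closed form: beta1 = 0.7 at G = 0.6 gives inverse-logit(0.42)."""
    disease = DiseaseModelSpec(intercept=0.0, causal_indices=(1,), effects=(0.7,))
    p = outcome_probability(np.array([0.6]), disease)
    assert p == pytest.approx(1 / (1 + np.exp(-0.42)), abs=1e-12)


def test_outcome_probability_monotone_in_effect():
    probs = [
        outcome_probability(
            np.array([0.6, 0.1]),
            DiseaseModelSpec(intercept=0.0, causal_indices=(1,), effects=(b,)),
        )
        for b in (0.5, 2.0, 10.0, 50.0)
    ]
    assert np.all(np.diff(probs) > 0) and probs[-1] > 0.999


def test_disease_model_validation():
    with pytest.raises(ValueError):
        DiseaseModelSpec(causal_indices=(1, 2), effects=(0.5,))
    with pytest.raises(ValueError):
        DiseaseModelSpec(causal_indices=(0,), effects=(0.5,))
    disease = DiseaseModelSpec(causal_indices=(11,), effects=(0.5,))
    with pytest.raises(ValueError):
        disease.validate_for(10)


def test_case_control_quotas_met(small_null_scenario):
    G, y = sample_case_control(small_null_scenario, seed=4)
    assert int(y.sum()) == small_null_scenario.n_cases
    assert int((1 - y).sum()) == small_null_scenario.n_controls
    assert G.n_samples == 120


def test_case_control_deterministic(small_null_scenario):
    G1, y1 = sample_case_control(small_null_scenario, seed=17)
    G2, y2 = sample_case_control(small_null_scenario, seed=17)
    np.testing.assert_array_equal(G1.values, G2.values)
    np.testing.assert_array_equal(y1, y2)


def test_null_phenotype_independent_of_methylation():
    """Point-biserial correlation near zero under the no-causal-CpG model."""
    marginals = [BetaMarginalSpec(0.6)] * 10
    sc = ScenarioSpec(
        marginals, CorrelationTarget.exchangeable(0.4, 10), DiseaseModelSpec(),
        n_cases=1000, n_controls=1000, label="null-check",
    )
    G, y = sample_case_control(sc, seed=1)
    yc = y - y.mean()
    for j in range(G.n_cpgs):
        g = G.values[:, j]
        r = (g - g.mean()) @ yc / (np.linalg.norm(g - g.mean()) * np.linalg.norm(yc))
        assert abs(r) < 0.08


def test_quota_exhaustion_reports_acceptance_rate():
    """An extreme intercept makes cases unattainable within the budget."""
    sc = ScenarioSpec(
        [BetaMarginalSpec(0.5)], CorrelationTarget(np.eye(1)),
        DiseaseModelSpec(intercept=-20.0), n_cases=50, n_controls=50,
        label="degenerate",
    )
    with pytest.raises(QuotaExhaustedError, match="acceptance rate"):
        sample_case_control(sc, seed=2, max_draw_factor=10)
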