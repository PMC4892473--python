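"""Oracle and contract tests for the seven set-based association tests."""

import numpy as np
import pingouin
import pytest
from scipy import stats

from cpgset import (
    MethylationMatrix,
    fit_null_logistic,
    hotelling_t2_test,
    kpca_test,
    logistic_lrt,
    minp_bonferroni_t_test,
    pca_reduce,
    pca_test,
    run_method,
    sir_decompose,
    sir_test,
    skat_test,
    spca_test,
)
from cpgset.settests.kernel import center_kernel, kernel_pc_scores, rbf_kernel
from cpgset.settests.skat import skat_null, skat_statistic


# ---------------------------------------------------------------- PCA

def test_pca_single_column_is_identity(rng):
    g = rng.random((20, 1))
    scores, k, explained = pca_reduce(g, 0.8)
    assert k == 1
    np.testing.assert_allclose(np.abs(scores[:, 0]), np.abs(g[:, 0] - g.mean()),
                               atol=1e-12)
    assert explained[0] == pytest.approx(1.0)


def test_pca_rank_one_structure(rng):
    g = rng.random((30, 1))
    G = np.column_stack([g, 0.25 + 0.5 * g])  # perfectly correlated pair
    scores, k, explained = pca_reduce(G, 0.8)
    assert k == 1
    assert explained[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_eigenvalues_match_covariance_oracle():
    """Component variances equal the eigenvalues of the sample covariance."""
    G = np.array([[0.1, 0.5, 0.9],
                  [0.2, 0.4, 0.7],
                  [0.8, 0.6, 0.2],
                  [0.9, 0.3, 0.4]])
    _, _, explained = pca_reduce(G, 1.0)
    oracle = np.sort(np.linalg.eigvalsh(np.cov(G, rowvar=False)))[::-1]
    np.testing.assert_allclose(explained * oracle.sum(), oracle, atol=1e-12)


def test_pca_full_threshold_equals_full_lrt(small_dataset):
    """With every PC retained the test is the p-df LRT on G itself."""
    G, y = small_dataset
    res = pca_test(G, y, variance_threshold=1.0)
    stat, df, p = logistic_lrt(y, None, G.values)
    assert res.df == df
    assert res.statistic == pytest.approx(stat, abs=1e-6)
    assert res.p_value == pytest.approx(p, abs=1e-8)


def test_pca_threshold_validation(small_dataset):
    G, y = small_dataset
    with pytest.raises(ValueError):
        pca_test(G, y, variance_threshold=0.0)
    with pytest.raises(ValueError):
        pca_reduce(np.full((10, 3), 0.5), 0.8)


# ---------------------------------------------------------------- KPCA

def test_rbf_kernel_identical_rows_and_range(rng):
    G = rng.random((10, 4))
    G[3] = G[7]
    K = rbf_kernel(G, sigma=0.5)
    assert K[3, 7] == pytest.approx(1.0)
    assert K.min() > 0 and K.max() <= 1.0 + 1e-12
    np.testing.assert_allclose(np.diag(K), 1.0)


def test_rbf_kernel_small_sigma_limit(rng):
    G = rng.random((8, 3))
    K = rbf_kernel(G, sigma=1e-12)
    np.testing.assert_allclose(K, 1.0, atol=1e-10)
    np.testing.assert_allclose(center_kernel(K), 0.0, atol=1e-9)


def test_center_kernel_matches_explicit_formula():
    """3x2 toy: double centering vs the formula evaluated with plain loops."""
    G = np.array([[0.1, 0.9], [0.4, 0.3], [0.8, 0.5]])
    K = rbf_kernel(G, sigma=2.0)
    n = 3
    expected = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            expected[i, j] = (K[i, j] - K[i, :].mean() - K[:, j].mean() + K.mean())
    np.testing.assert_allclose(center_kernel(K), expected, atol=1e-14)
    # centered kernel must be PSD up to numerical tolerance
    assert np.linalg.eigvalsh(center_kernel(K)).min() > -1e-12


def test_linear_kernel_spans_pca_subspace(small_dataset):
    """Kernel PCA with a linear kernel reproduces ordinary PCA scores."""
    G, y = small_dataset
    pc_scores, k, _ = pca_reduce(G.values, 0.8)
    kk_scores, k2, _ = kernel_pc_scores(G.values @ G.values.T, 0.8)
    # same retained dimension and unit canonical correlations
    assert k2 == k
    qa, _ = np.linalg.qr(pc_scores)
    qb, _ = np.linalg.qr(kk_scores[:, :k])
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    np.testing.assert_allclose(sv, 1.0, atol=1e-8)
    res_lin = kpca_test(G, y, kernel="linear", variance_threshold=0.8)
    res_pca = pca_test(G, y, variance_threshold=0.8)
    assert res_lin.p_value == pytest.approx(res_pca.p_value, abs=1e-8)


def test_kpca_tolerates_duplicate_rows(small_dataset):
    G, y = small_dataset
    values = G.values.copy()
    values[1] = values[0]
    res = kpca_test(values, y)
    assert 0.0 <= res.p_value <= 1.0


def test_kpca_large_n_path_matches_full_eigh(rng):
    """The iterative eigenpair route (n > 512) agrees with the dense eigh."""
    values = rng.random((600, 5))
    y = rng.integers(0, 2, 600)
    y[0], y[1] = 0, 1
    K = rbf_kernel(values, 0.01)
    scores_big, k_big, _ = kernel_pc_scores(K, 0.8)
    vals, vecs = np.linalg.eigh(center_kernel(K))
    vals, vecs = vals[::-1], vecs[:, ::-1]
    explained = vals / vals.sum()
    k_ref = int(np.searchsorted(np.cumsum(explained), 0.8 - 1e-12) + 1)
    assert k_big == k_ref
    np.testing.assert_allclose(
        np.abs(scores_big), np.abs(vecs[:, :k_ref] * np.sqrt(vals[:k_ref])),
        atol=1e-6,
    )


# ---------------------------------------------------------------- SKAT

def test_skat_toy_statistic_by_direct_arithmetic():
    y = np.array([1, 0, 1, 0], dtype=float)
    G = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=float)
    null = fit_null_logistic(y)
    np.testing.assert_allclose(null.fitted_means, 0.5)
    assert skat_statistic(y, null, G) == pytest.approx(1.0, abs=1e-12)


def test_skat_zero_statistic_cases(rng):
    y = rng.integers(0, 2, 40).astype(float)
    y[:2] = [0, 1]
    null = fit_null_logistic(y)
    # constant columns: G'(y - mu) = c * sum(residuals) = 0 with an intercept
    assert skat_statistic(y, null, np.full((40, 3), 0.7)) == pytest.approx(0.0, abs=1e-18)


def test_skat_single_cpg_equals_score_test(small_dataset):
    """p = 1: SKAT is the squared logistic score test of that CpG."""
    G, y = small_dataset
    g = G.values[:, [0]]
    res = skat_test(g, y)
    null = fit_null_logistic(y)
    lam = skat_null(null, g).eigenvalues
    assert lam.size == 1
    oracle_p = stats.chi2.sf(res.statistic / lam[0], 1)
    assert res.p_value == pytest.approx(oracle_p, abs=1e-6)


def test_skat_weight_scale_invariance(small_dataset):
    G, y = small_dataset
    null = fit_null_logistic(y)
    w1 = np.ones(G.n_cpgs)
    q1 = skat_statistic(y, null, G, w1)
    q2 = skat_statistic(y, null, G, 2 * w1)
    assert q2 == pytest.approx(4 * q1, rel=1e-12)
    lam1 = skat_null(null, G, w1).eigenvalues
    lam2 = skat_null(null, G, 2 * w1).eigenvalues
    np.testing.assert_allclose(lam2, 4 * lam1, rtol=1e-10)
    p1 = skat_test(G, y, weights=w1).p_value
    p2 = skat_test(G, y, weights=2 * w1).p_value
    assert p1 == pytest.approx(p2, abs=1e-9)


def test_skat_constant_set_is_degenerate():
    y = np.array([0, 1] * 10, dtype=float)
    with pytest.raises(ValueError, match="degenerate"):
        skat_test(np.full((20, 2), 0.5), y)


# ---------------------------------------------------------------- SIR

def test_sir_binary_outcome_rank_one(small_dataset):
    G, y = small_dataset
    dec = sir_decompose(G, y)
    assert dec.n_slices == 2
    assert dec.slice_proportions.sum() == pytest.approx(1.0)
    # two slice means on a line: one nonzero eigenvalue
    assert dec.eigenvalues[1] < 1e-10 * max(dec.eigenvalues[0], 1e-30) + 1e-12


def test_sir_toy_matches_hand_computation():
    """8-row, p = 2 toy vs the definition evaluated step by step."""
    G = np.array([[0.10, 0.20], [0.20, 0.35], [0.30, 0.30], [0.40, 0.55],
                  [0.60, 0.50], [0.70, 0.75], [0.80, 0.70], [0.90, 0.95]])
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    dec = sir_decompose(G, y)
    # oracle: standardize, slice means, weighted between-slice covariance
    cov = np.cov(G, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    W = (vecs / np.sqrt(vals)) @ vecs.T
    Z = (G - G.mean(axis=0)) @ W
    m0, m1 = Z[y == 0].mean(axis=0), Z[y == 1].mean(axis=0)
    M = 0.5 * np.outer(m0, m0) + 0.5 * np.outer(m1, m1)
    oracle_vals = np.sort(np.linalg.eigvalsh(M))[::-1]
    np.testing.assert_allclose(dec.slice_means, [m0, m1], atol=1e-10)
    np.testing.assert_allclose(dec.eigenvalues, np.clip(oracle_vals, 0, None),
                               atol=1e-10)


def test_sir_single_cpg_equals_standardized_mean_difference(small_dataset):
    G, y = small_dataset
    g = G.values[:, [2]]
    res = sir_test(g, y)
    n = len(y)
    z = (g[:, 0] - g.mean()) / np.std(g[:, 0], ddof=1)
    p1, p0 = y.mean(), 1 - y.mean()
    oracle = n * (p1 * z[y == 1].mean() ** 2 + p0 * z[y == 0].mean() ** 2)
    assert res.statistic == pytest.approx(oracle, abs=1e-8)
    assert res.df == 1


def test_sir_null_eigenvalues_vanish(rng):
    G = rng.random((2000, 4))
    y = rng.integers(0, 2, 2000)
    dec = sir_decompose(G, y)
    assert dec.eigenvalues.max() < 30.0 / 2000  # order 1/n under independence


def test_sir_constant_response_rejected(small_dataset):
    G, _ = small_dataset
    with pytest.raises(ValueError):
        sir_test(G, np.zeros(G.n_samples))


# ---------------------------------------------------------------- Hotelling T2

def test_hotelling_identical_groups():
    block = np.random.default_rng(0).random((15, 3))
    G = np.vstack([block, block])
    y = np.array([1] * 15 + [0] * 15)
    res = hotelling_t2_test(G, y)
    assert res.statistic == pytest.approx(0.0, abs=1e-18)
    assert res.p_value == pytest.approx(1.0)


def test_hotelling_univariate_equals_squared_t(small_dataset):
    G, y = small_dataset
    g = G.values[:, [4]]
    res = hotelling_t2_test(g, y)
    t, p = stats.ttest_ind(g[y == 1, 0], g[y == 0, 0], equal_var=True)
    assert res.statistic == pytest.approx(t**2, rel=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_hotelling_matches_pingouin(small_dataset):
    """Independent multivariate two-sample oracle."""
    G, y = small_dataset
    res = hotelling_t2_test(G, y)
    oracle = pingouin.multivariate_ttest(G.values[y == 1], G.values[y == 0])
    assert res.statistic == pytest.approx(float(oracle["T2"].iloc[0]), rel=1e-8)
    assert res.p_value == pytest.approx(float(oracle["pval"].iloc[0]), abs=1e-10)


def test_hotelling_needs_enough_observations(rng):
    G = rng.random((8, 6))
    y = np.array([1] * 4 + [0] * 4)
    with pytest.raises(ValueError, match="at least"):
        hotelling_t2_test(G, y)


# ---------------------------------------------------------------- min-p t

def test_minp_single_cpg_equals_t_test(small_dataset):
    G, y = small_dataset
    g = G.values[:, [1]]
    res = minp_bonferroni_t_test(g, y)
    _, p = stats.ttest_ind(g[y == 1, 0], g[y == 0, 0], equal_var=True)
    assert res.p_value == pytest.approx(p, abs=1e-12)


def test_minp_bonferroni_arithmetic(small_dataset):
    G, y = small_dataset
    res = minp_bonferroni_t_test(G, y)
    _, pvals = stats.ttest_ind(G.values[y == 1], G.values[y == 0],
                               axis=0, equal_var=True)
    assert res.p_value == pytest.approx(min(1.0, G.n_cpgs * pvals.min()), abs=1e-12)
    assert res.detail["min_p"] == pytest.approx(pvals.min(), abs=1e-15)


def test_minp_drops_constant_columns(small_dataset, caplog):
    G, y = small_dataset
    values = np.column_stack([G.values, np.full(G.n_samples, 0.5)])
    res = minp_bonferroni_t_test(values, y)
    assert res.detail["n_tests"] == G.n_cpgs  # the constant column is excluded
    with pytest.raises(ValueError):
        minp_bonferroni_t_test(np.full((G.n_samples, 2), 0.25), y)


# ---------------------------------------------------------------- SPCA

def test_spca_selects_separated_cpg(rng):
    """A strongly differential CpG is always at the top of the screen."""
    n = 60
    y = np.array([1] * 30 + [0] * 30)
    G = rng.random((n, 5)) * 0.2 + 0.4
    G[:, 2] = np.where(y == 1, 0.9, 0.1) + rng.normal(0, 0.01, n)
    G = np.clip(G, 0, 1)
    res = spca_test(G, y, n_permutations=99, seed=1)
    assert "cpg_3" in res.detail["selected_cpgs"]
    assert res.p_value == pytest.approx(1 / 100)


def test_spca_permutation_floor(rng):
    n = 80
    y = np.array([1] * 40 + [0] * 40)
    G = rng.random((n, 4)) * 0.1 + 0.45
    G[:, 0] += np.where(y == 1, 0.3, -0.3)
    G = np.clip(G, 0, 1)
    res = spca_test(G, y, n_permutations=999, seed=3)
    assert res.p_value == pytest.approx(1 / 1000)
    assert res.detail["n_permutations"] == 999


def test_spca_deterministic_given_seed(small_dataset):
    G, y = small_dataset
    r1 = spca_test(G, y, n_permutations=99, seed=42)
    r2 = spca_test(G, y, n_permutations=99, seed=42)
    assert r1.p_value == r2.p_value and r1.statistic == r2.statistic


def test_spca_requires_enough_permutations(small_dataset):
    G, y = small_dataset
    with pytest.raises(ValueError):
        spca_test(G, y, n_permutations=10)


def test_spca_cv_selection_runs(small_dataset):
    G, y = small_dataset
    res = spca_test(G, y, n_permutations=99, seed=0, selection="cv")
    assert 0 < res.p_value <= 1


def test_spca_null_calibration(rng):
    """Permutation p-values reject at close to the nominal 5% under the null."""
    reps, n = 250, 80
    rejections = 0
    for i in range(reps):
        y = np.array([1] * 40 + [0] * 40)
        G = rng.random((n, 6))
        if spca_test(G, y, n_permutations=99, seed=1000 + i).p_value <= 0.05:
            rejections += 1
    rate = rejections / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


# ---------------------------------------------------------------- cross-cutting

@pytest.mark.parametrize("method", ["pca", "kpca", "skat", "sir", "t2", "minp_t"])
def test_sample_permutation_invariance(small_dataset, method, rng):
    """Consistently reordering samples leaves each statistic unchanged."""
    G, y = small_dataset
    perm = rng.permutation(G.n_samples)
    res1 = run_method(method, G.values, y)
    res2 = run_method(method, G.values[perm], y[perm])
    assert res1.statistic == pytest.approx(res2.statistic, abs=1e-8, rel=1e-10)
    assert res1.p_value == pytest.approx(res2.p_value, abs=1e-10)


@pytest.mark.parametrize("method", ["pca", "spca", "kpca", "skat", "sir", "t2", "minp_t"])
def test_every_method_returns_valid_result(small_dataset, method):
    G, y = small_dataset
    res = run_method(method, G, y, seed=7,
                     **({"n_permutations": 99} if method == "spca" else {}))
    assert 0.0 <= res.p_value <= 1.0
    assert np.isfinite(res.statistic)


def test_unknown_method_rejected(small_dataset):
    G, y = small_dataset
    with pytest.raises(KeyError):
        run_method("anova", G, y)


def test_matrix_container_validation():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        MethylationMatrix(np.array([[0.5, 1.2]]), ["a", "b"], ["s1"])
    with pytest.raises(ValueError, match="missing"):
        MethylationMatrix(np.array([[0.5, np.nan]]), ["a", "b"], ["s1"])
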