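"""Supervised PCA set test with a permutation null.

Supervised PCA screens the CpG set down to the columns most associated with
the outcome (univariate logistic score statistics), takes the first
principal component of the retained columns, and tests the Wald statistic
T = beta1-hat / s.e.(beta1-hat) of the logistic regression of the phenotype
on PC1.  Because the screening step is outcome-driven, T is not
t-distributed; the p-value here comes from a full-procedure permutation
null: the phenotype labels are permuted and the *entire* pipeline
(screening, threshold selection, PC1 extraction, Wald fit) is recomputed for
each permutation, so the selection bias is built into the reference
distribution.

The screening threshold is adaptive: the retained fraction is taken from
``screen_fraction_grid`` so as to maximize |T| ("max" rule, default), or by
K-fold cross-validated held-out likelihood improvement ("cv").  Either rule
is applied identically to the observed and the permuted data.
"""

from __future__ import annotations

import numpy as np

from ..containers import SetTestResult
from ..logistic import fit_logistic, fit_null_logistic, score_statistics
from ._common import as_methylation_array, check_phenotype, drop_zero_variance

__all__ = ["spca_test"]

DEFAULT_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def _pc1(centered: np.ndarray) -> np.ndarray:
    if centered.shape[1] == 1:
        return centered[:, 0]
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    return U[:, 0] * s[0]


def _pc1_from_gram(centered: np.ndarray, gram: np.ndarray, idx: np.ndarray
                   ) -> np.ndarray:
    """First PC score of centered[:, idx] via the precomputed p x p Gram matrix.

    The Gram matrix C'C does not depend on the phenotype, so it is computed
    once per spca_test call and reused across every screening subset and
    every permutation; extracting PC1 then costs one m x m eigendecomposition
    and one n x m product.
    """
    if idx.size == 1:
        return centered[:, idx[0]]
    sub = gram[np.ix_(idx, idx)]
    vals, vecs = np.linalg.eigh(sub)
    return centered[:, idx] @ vecs[:, -1]


def _wald_t(y: np.ndarray, null_design: np.ndarray, pc1: np.ndarray) -> float:
    if null_design.shape[1] == 1:
        return _wald_t_intercept_only(y, pc1)
    design = np.column_stack([null_design, pc1])
    try:
        fit = fit_logistic(y, design)
    except RuntimeError:
        return np.inf  # separation on PC1: maximal evidence
    se = np.sqrt(max(fit.cov[-1, -1], 1e-300))
    return float(fit.coef[-1] / se)


def _wald_t_intercept_only(y: np.ndarray, x: np.ndarray, max_iter: int = 40
                           ) -> float:
    """Wald z of the slope in logit P(y=1) = b0 + b1 x, tight Newton loop.

    Specialized two-parameter fit used on the permutation-null hot path
    (thousands of fits per set test); the 2x2 information solve is done in
    closed form.
    """
    x = x / max(x.std(), 1e-300)  # Wald z is invariant to predictor scale
    ybar = y.mean()
    b0 = np.log(ybar / (1 - ybar))
    b1 = 0.0
    for _ in range(max_iter):
        eta = np.clip(b0 + b1 * x, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = y - mu
        w = mu * (1.0 - mu)
        g0, g1 = r.sum(), r @ x
        wx = w @ x
        s0, s1, s2 = w.sum(), wx, (w * x) @ x
        det = s0 * s2 - s1 * s1
        if det <= 1e-300:
            return np.inf  # separation: unbounded slope
        d0 = min(max((s2 * g0 - s1 * g1) / det, -2.0), 2.0)
        d1 = min(max((-s1 * g0 + s0 * g1) / det, -2.0), 2.0)
        b0 += d0
        b1 += d1
        if abs(d0) < 1e-8 and abs(d1) < 1e-8:
            break
    eta = np.clip(b0 + b1 * x, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    wx = w @ x
    s0, s1, s2 = w.sum(), wx, (w * x) @ x
    det = s0 * s2 - s1 * s1
    if det <= 1e-300 or abs(b1) > 25:
        return np.inf
    se = np.sqrt(s0 / det)
    return float(b1 / se)


def _subset_sizes(p: int, fractions) -> list[int]:
    sizes = sorted({max(1, int(np.ceil(f * p))) for f in fractions})
    return [m for m in sizes if m <= p]


def _batch_wald(Y: np.ndarray, X: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Wald z of the slope of logit P(y=1) = b0 + b1 x, one fit per column.

    Vectorized two-parameter Newton iteration across B (phenotype, PC1)
    pairs at once; the 2x2 information solves are closed-form.  Columns
    that separate (diverging slope) get +/-inf, i.e. maximal evidence.
    """
    n, B = Y.shape
    # standardize the predictor: the Wald z is scale-invariant and the
    # separation threshold below becomes dimensionless (log-odds per sd)
    X = X / np.maximum(X.std(axis=0), 1e-300)
    ybar = Y.mean(axis=0)
    b0 = np.log(ybar / (1 - ybar))
    b1 = np.zeros(B)
    s0 = s1 = s2 = det = None
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + X * b1[None, :], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        R = Y - mu
        W = mu * (1.0 - mu)
        WX = W * X
        g0 = R.sum(axis=0)
        g1 = np.einsum("ij,ij->j", R, X)
        s0 = W.sum(axis=0)
        s1 = WX.sum(axis=0)
        s2 = np.einsum("ij,ij->j", WX, X)
        det = np.maximum(s0 * s2 - s1 * s1, 1e-300)
        # damped Newton: undamped steps oscillate on flat likelihoods, which
        # would spuriously push finite slopes past the separation threshold
        d0 = np.clip((s2 * g0 - s1 * g1) / det, -2.0, 2.0)
        d1 = np.clip((-s1 * g0 + s0 * g1) / det, -2.0, 2.0)
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(), np.abs(d1).max()) < 1e-8:
            break
    se = np.sqrt(s0 / det)
    t = b1 / se
    t[np.abs(b1) > 25] = np.inf
    return t


def _permutation_pvalue_fast(y, sizes, centered, gram, pc_cache, n_permutations,
                             rng) -> tuple[float, float, np.ndarray]:
    """Full-procedure permutation p-value, batched across permutations.

    Valid for the intercept-only null with the "max" selection rule: the
    screening score statistics reduce to scaled centered cross-products
    (one matrix product for all permutations), PC1 vectors are cached by
    subset, and the Wald fits run as one batched Newton per subset size.
    """
    n, p = centered.shape
    B = n_permutations
    Y = np.empty((n, B + 1))
    Y[:, 0] = y
    for b in range(1, B + 1):
        Y[:, b] = rng.permutation(y)
    col_ss = np.einsum("ij,ij->j", centered, centered)
    zabs = np.abs(centered.T @ Y) / np.sqrt(np.maximum(col_ss, 1e-300))[:, None]
    orders = np.argsort(-zabs, axis=0, kind="stable")
    T = np.zeros(B + 1)
    best_first = orders[:sizes[0], 0]
    for m in sizes:
        keys = orders[:m, :]
        X = np.empty((n, B + 1))
        for b in range(B + 1):
            key = tuple(np.sort(keys[:, b]))
            pc = pc_cache.get(key)
            if pc is None:
                pc = _pc1_from_gram(centered, gram, np.sort(keys[:, b]))
                pc_cache[key] = pc
            X[:, b] = pc
        t = _batch_wald(Y, X)
        better = np.abs(t) > np.abs(T)
        if better[0]:
            best_first = keys[:, 0]
        T = np.where(better, t, T)
    t_obs = T[0]
    exceed = int(np.sum(np.abs(T[1:]) >= abs(t_obs) - 1e-12))
    return t_obs, (1 + exceed) / (B + 1), best_first


def _statistic_max(values, y, covariates, sizes, centered, gram, pc_cache):
    if covariates is None:
        # intercept-only null: the score statistic reduces to the scaled
        # centered cross-product, so screening is a single matrix product
        ybar = y.mean()
        col_ss = np.einsum("ij,ij->j", centered, centered)
        z = (centered.T @ y) / np.sqrt(np.maximum(ybar * (1 - ybar) * col_ss, 1e-300))
        null_design = np.ones((y.size, 1))
    else:
        null = fit_null_logistic(y, covariates)
        z = score_statistics(values, null)
        null_design = null.design
    order = np.argsort(-np.abs(z), kind="stable")
    best_t, best_idx = 0.0, order[:1]
    for m in sizes:
        idx = order[:m]
        key = tuple(sorted(idx))
        pc1 = pc_cache.get(key)
        if pc1 is None:
            pc1 = _pc1_from_gram(centered, gram, idx)
            pc_cache[key] = pc1
        t = _wald_t(y, null_design, pc1)
        if abs(t) > abs(best_t):
            best_t, best_idx = t, idx
    return best_t, best_idx


def _statistic_cv(values, y, covariates, sizes, cv_folds, rng):
    """Fraction chosen by K-fold cross-validated held-out log-likelihood."""
    n = values.shape[0]
    folds = np.resize(np.arange(cv_folds), n)
    rng.shuffle(folds)
    gains = np.zeros(len(sizes))
    for f in range(cv_folds):
        test = folds == f
        train = ~test
        null_tr = fit_null_logistic(y[train], None if covariates is None
                                    else np.asarray(covariates)[train])
        z = score_statistics(values[train], null_tr)
        order = np.argsort(-np.abs(z), kind="stable")
        mu_tr = values[train].mean(axis=0)
        centered_tr = values[train] - mu_tr
        p_null = y[train].mean()
        ll_null = np.sum(y[test] * np.log(p_null) + (1 - y[test]) * np.log1p(-p_null))
        for s_i, m in enumerate(sizes):
            idx = order[:m]
            sub = centered_tr[:, idx]
            if sub.shape[1] == 1:
                v = np.ones(1)
            else:
                _, _, Vt = np.linalg.svd(sub, full_matrices=False)
                v = Vt[0]
            pc_tr = sub @ v
            pc_te = (values[test][:, idx] - mu_tr[idx]) @ v
            try:
                fit = fit_logistic(y[train], np.column_stack([null_tr.design, pc_tr]))
            except RuntimeError:
                continue
            design_te = np.column_stack([np.ones(test.sum()), pc_te])
            eta = design_te @ np.array([fit.coef[0], fit.coef[-1]])
            mu = 1 / (1 + np.exp(-np.clip(eta, -700, 700)))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            ll = np.sum(y[test] * np.log(mu) + (1 - y[test]) * np.log1p(-mu))
            gains[s_i] += ll - ll_null
    m_star = sizes[int(np.argmax(gains))]
    null = fit_null_logistic(y, covariates)
    z = score_statistics(values, null)
    order = np.argsort(-np.abs(z), kind="stable")
    idx = order[:m_star]
    centered = values - values.mean(axis=0)
    return _wald_t(y, null.design, _pc1(centered[:, idx])), idx


def spca_test(
    G,
    y,
    covariates=None,
    screen_fraction_grid=DEFAULT_FRACTIONS,
    n_permutations: int = 199,
    seed: int = 0,
    *,
    selection: str = "max",
    cv_folds: int = 5,
) -> SetTestResult:
    """Supervised-PCA set test with a full-procedure permutation p-value.

    ``n_permutations`` must be at least 99; p = (1 + #{|T_perm| >= |T_obs|})
    / (n_permutations + 1), so the smallest attainable p-value is
    1/(n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations for a stable p-value")
    if selection not in ("max", "cv"):
        raise ValueError("selection must be 'max' or 'cv'")
    values, cpg_ids = as_methylation_array(G)
    y = check_phenotype(y, values.shape[0])
    values, cpg_ids = drop_zero_variance(values, cpg_ids, "SPCA")
    sizes = _subset_sizes(values.shape[1], screen_fraction_grid)
    rng = np.random.default_rng(seed)
    centered = values - values.mean(axis=0)
    gram = centered.T @ centered
    pc_cache: dict[tuple, np.ndarray] = {}

    if selection == "max" and covariates is None:
        t_obs, p, selected = _permutation_pvalue_fast(
            y, sizes, centered, gram, pc_cache, n_permutations, rng
        )
    else:
        def statistic(yy):
            if selection == "max":
                return _statistic_max(values, yy, covariates, sizes, centered,
                                      gram, pc_cache)
            return _statistic_cv(values, yy, covariates, sizes, cv_folds, rng)

        t_obs, selected = statistic(y)
        exceed = 0
        for _ in range(n_permutations):
            t_perm, _ = statistic(rng.permutation(y))
            if abs(t_perm) >= abs(t_obs) - 1e-12:
                exceed += 1
        p = (1 + exceed) / (n_permutations + 1)
    stat = float(t_obs) if np.isfinite(t_obs) else np.sign(t_obs) * 1e12
    return SetTestResult(
        method="SPCA", statistic=float(stat), df=None, p_value=p,
        detail={
            "selected_cpgs": [cpg_ids[j] for j in selected],
            "n_selected": int(len(selected)),
            "n_permutations": n_permutations,
            "selection": selection,
        },
    )
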