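"""Newton (IRLS) logistic regression and the k-df likelihood-ratio test.

A minimal, fast logistic fitter is the workhorse of several set tests
(PCA/KPCA likelihood-ratio tests, SKAT's null model, SPCA's screening and
PC1 fit).  The Monte Carlo harness calls it tens of thousands of times per
benchmark, so it is written directly on numpy rather than through a general
GLM layer; agreement with an independent iterative fit is part of the test
suite's oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LogisticFit",
    "NullModel",
    "PerfectSeparationError",
    "fit_logistic",
    "fit_null_logistic",
    "logistic_lrt",
    "score_statistics",
]


class PerfectSeparationError(RuntimeError):
    """Raised when the likelihood diverges (complete/quasi separation)."""


@dataclass
class LogisticFit:
    coef: np.ndarray          # coefficients, intercept first
    fitted: np.ndarray        # fitted probabilities mu_i
    log_likelihood: float
    cov: np.ndarray           # inverse observed information
    n_iter: int
    converged: bool


@dataclass
class NullModel:
    """Null logistic model Logit P(y=1) = a0 + a'X (no CpG terms).

    ``design`` includes the intercept column; ``fitted_means`` are the
    mu-hat used by the score-type statistics (SKAT, SPCA screening).
    """

    y: np.ndarray
    design: np.ndarray
    fitted_means: np.ndarray
    coef: np.ndarray
    log_likelihood: float


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def fit_logistic(
    y: np.ndarray,
    design: np.ndarray,
    *,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of y on a full design matrix.

    Newton-Raphson with step-halving; ``design`` must already contain the
    intercept column.  Raises PerfectSeparationError when fitted
    probabilities collapse to 0/1 (monotone likelihood).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    # warm start for the intercept keeps iteration counts low
    ybar = y.mean()
    if 0 < ybar < 1 and np.allclose(X[:, 0], 1.0):
        beta[0] = np.log(ybar / (1 - ybar))
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = _bernoulli_loglik(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving line search on the log-likelihood
        new_ll = -np.inf
        for half in range(30):
            cand = beta + step
            eta = X @ cand
            mu_c = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            new_ll = _bernoulli_loglik(y, mu_c)
            if new_ll >= ll - 1e-13:
                break
            step *= 0.5
        beta, mu = cand, mu_c
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    w = mu * (1.0 - mu)
    # complete separation: every fitted probability pinned to its label's
    # boundary (the likelihood sup is 0 and coefficients diverge)
    if np.max(w) < 1e-6 and np.all((mu > 0.5) == (y > 0.5)):
        raise PerfectSeparationError(
            "logistic fit diverged: data are perfectly separated"
        )
    if not converged and np.min(w) < 1e-10:
        raise PerfectSeparationError(
            "logistic fit diverged: data are (quasi-)separated"
        )
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return LogisticFit(beta, mu, ll, cov, it, converged)


def _null_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("covariate matrix does not match the sample count")
    return np.column_stack([np.ones(n), X])


def fit_null_logistic(y: np.ndarray, covariates: np.ndarray | None = None) -> NullModel:
    """Fit the null disease model (intercept + optional covariates only)."""
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("phenotype must be coded 0/1")
    if classes.size < 2:
        raise ValueError("phenotype contains a single class; cannot fit a null model")
    X = _null_design(y.size, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("null design (intercept + covariates) is rank deficient")
    if X.shape[1] == 1:
        # intercept-only MLE is the sample prevalence
        mu = np.full(y.size, y.mean())
        coef = np.array([np.log(y.mean() / (1 - y.mean()))])
        ll = _bernoulli_loglik(y, mu)
        return NullModel(y, X, mu, coef, ll)
    fit = fit_logistic(y, X)
    return NullModel(y, X, fit.fitted, fit.coef, fit.log_likelihood)


def _independent_columns(base: np.ndarray, Z: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of Z columns not (numerically) in the span of [base, Z[:previous]]."""
    keep: list[int] = []
    Q, _ = np.linalg.qr(base)
    basis = Q
    for j in range(Z.shape[1]):
        z = Z[:, j]
        norm = np.linalg.norm(z)
        if norm <= tol * np.sqrt(z.size):
            continue
        resid = z - basis @ (basis.T @ z)
        if np.linalg.norm(resid) > tol * max(norm, 1.0):
            keep.append(j)
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
    return np.asarray(keep, dtype=int)


def logistic_lrt(
    y: np.ndarray,
    covariates: np.ndarray | None,
    Z: np.ndarray,
) -> tuple[float, int, float]:
    """k-df likelihood-ratio test for adding score columns Z to the null design.

    Columns of Z collinear with the null design (or each other) are dropped;
    the df is the number of linearly independent added columns.  Returns
    ``(statistic, df, p_value)`` with the chi-square upper-tail p-value.
    """
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != y.size:
        Z = Z.T
    null = fit_null_logistic(y, covariates)
    keep = _independent_columns(null.design, Z)
    if keep.size == 0:
        return 0.0, 0, 1.0
    full_design = np.column_stack([null.design, Z[:, keep]])
    try:
        full = fit_logistic(y, full_design)
        ll_full = full.log_likelihood
    except PerfectSeparationError:
        # separated alternative: likelihood sup is the saturated bound; the
        # LRT statistic is still well-defined via the limiting likelihood
        ll_full = 0.0
    stat = max(0.0, 2.0 * (ll_full - null.log_likelihood))
    df = int(keep.size)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def score_statistics(G: np.ndarray, null: NullModel) -> np.ndarray:
    """Per-column logistic score z-statistics given a fitted null model.

    For CpG column g, the efficient score is g'(y - mu) with variance
    g~' V g~ where V = diag(mu(1-mu)) and g~ is g residualized against the
    null design in the V inner product.  Standard normal under the null;
    used by SPCA's supervised screening.
    """
    G = np.asarray(G, dtype=float)
    y, X, mu = null.y, null.design, null.fitted_means
    v = mu * (1.0 - mu)
    r = y - mu
    XtVX = (X * v[:, None]).T @ X
    XtVG = (X * v[:, None]).T @ G
    coef = np.linalg.solve(XtVX, XtVG)
    Gt = G - X @ coef
    num = Gt.T @ r
    den = np.einsum("ij,ij->j", Gt * v[:, None], Gt)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(den > 0, num / np.sqrt(np.maximum(den, 1e-300)), 0.0)
    return z
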