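"""SKAT: variance-component score test with a linear methylation kernel.

Under the logistic model logit P(y=1) = a0 + a'X + b'G, each CpG effect b_j
is modeled as a random effect with mean 0 and variance w_j * tau; testing
the set reduces to H0: tau = 0, a variance-component score test whose
statistic is the quadratic form

    Q = (y - mu)' G W W G' (y - mu),

with mu the fitted means of the null logistic model and W = diag(w_j)
(all-ones weights by default, every CpG weighted equally).  Under H0,
Q is distributed as a weighted mixture of chi-square(1) variables with
weights given by the spectrum of (GW)' P0 (GW), where
P0 = V - V Xt (Xt' V Xt)^-1 Xt' V is the working-model projection,
V = diag(mu (1 - mu)) and Xt the null design.  The tail probability comes
from exact characteristic-function inversion (Imhof) with a moment-matching
fallback; see :mod:`cpgset.quadform`.
"""

from __future__ import annotations

import numpy as np

from ..containers import SetTestResult
from ..logistic import NullModel, fit_null_logistic
from ..quadform import QuadFormNull, quadform_pvalue
from ._common import as_methylation_array, check_phenotype

__all__ = ["skat_statistic", "skat_null", "skat_test"]


def skat_statistic(y, null: NullModel, G, weights=None) -> float:
    """Q = ||W G'(y - mu-hat)||^2, computed without forming the n x n kernel."""
    values, _ = as_methylation_array(G)
    w = _weights(values.shape[1], weights)
    score = values.T @ (np.asarray(y, dtype=float) - null.fitted_means)
    return float(np.sum((w * score) ** 2))


def _weights(p: int, weights) -> np.ndarray:
    if weights is None:
        return np.ones(p)
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != p:
        raise ValueError(f"{w.size} weights for {p} CpGs")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    return w


def skat_null(null: NullModel, G, weights=None) -> QuadFormNull:
    """Mixture-of-chi-square weights: spectrum of (GW)' P0 (GW)."""
    values, _ = as_methylation_array(G)
    w = _weights(values.shape[1], weights)
    B = values * w[None, :]
    v = null.fitted_means * (1.0 - null.fitted_means)
    X = null.design
    VB = B * v[:, None]
    XtVX = (X * v[:, None]).T @ X
    XtVB = (X * v[:, None]).T @ B
    M = B.T @ VB - XtVB.T @ np.linalg.solve(XtVX, XtVB)
    lam = np.linalg.eigvalsh((M + M.T) / 2)
    top = lam.max()
    if top <= 0:
        raise ValueError("degenerate SKAT null: projected kernel has no "
                         "positive eigenvalue (constant CpG set?)")
    lam = lam[lam > 1e-10 * top]
    return QuadFormNull(lam)


def skat_test(G, y, covariates=None, weights=None) -> SetTestResult:
    """SKAT set test with equal weights by default."""
    values, _ = as_methylation_array(G)
    y = check_phenotype(y, values.shape[0])
    null = fit_null_logistic(y, covariates)
    q = skat_statistic(y, null, values, weights)
    qnull = skat_null(null, values, weights)
    p, info = quadform_pvalue(q, qnull, return_info=True)
    return SetTestResult(
        method="SKAT", statistic=q, df=None, p_value=p,
        detail={
            "eigenvalues": qnull.eigenvalues.tolist(),
            "pvalue_method": info["method"],
        },
    )
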