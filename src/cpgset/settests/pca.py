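"""PCA set test: k-df logistic likelihood-ratio test on leading components.

The CpG columns are centered (not variance-scaled: beta-values already share
the [0, 1] scale) and the smallest number k of leading principal components
whose cumulative variance fraction reaches the threshold (default 80%) is
retained.  Disease association is then tested by a k-df likelihood-ratio
test of the logistic regression of the phenotype on the k component scores,
given the null design (intercept + optional covariates).
"""

from __future__ import annotations

import numpy as np

from ..containers import SetTestResult
from ..logistic import logistic_lrt
from ._common import as_methylation_array, check_phenotype, drop_zero_variance

__all__ = ["pca_reduce", "pca_test"]


def pca_reduce(
    G, variance_threshold: float = 0.8, *, scale: bool = False
) -> tuple[np.ndarray, int, np.ndarray]:
    """Principal-component scores retaining a cumulative variance fraction.

    Returns ``(scores, k, explained)`` where ``scores`` is n x k, ``k`` is
    the smallest number of leading components whose cumulative explained
    variance fraction is at least ``variance_threshold`` and ``explained``
    holds the per-component fractions (all components).  With ``scale`` the
    columns are standardized first (correlation-matrix PCA).
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must lie in (0, 1]")
    values, _ = as_methylation_array(G)
    centered = values - values.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot scale zero-variance columns")
        centered = centered / sd
    if not centered.any():
        raise ValueError("all CpG columns have zero variance")
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    n = values.shape[0]
    eigenvalues = s**2 / (n - 1)
    explained = eigenvalues / eigenvalues.sum()
    k = int(np.searchsorted(np.cumsum(explained), variance_threshold - 1e-12) + 1)
    k = min(k, int(np.sum(s > s[0] * 1e-12)))
    scores = U[:, :k] * s[:k]
    return scores, k, explained


def pca_test(G, y, covariates=None, variance_threshold: float = 0.8) -> SetTestResult:
    """PCA set test: k-df LRT of the phenotype on retained PC scores."""
    values, cpg_ids = as_methylation_array(G)
    y = check_phenotype(y, values.shape[0])
    values, cpg_ids = drop_zero_variance(values, cpg_ids, "PCA")
    scores, k, explained = pca_reduce(values, variance_threshold)
    stat, df, p = logistic_lrt(y, covariates, scores)
    return SetTestResult(
        method="PCA", statistic=stat, df=df, p_value=p,
        detail={
            "k_retained": k,
            "explained_fraction": float(explained[:k].sum()),
            "variance_threshold": variance_threshold,
        },
    )
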