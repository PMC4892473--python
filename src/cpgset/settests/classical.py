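"""Classical comparison tests: Hotelling's T-squared and min-p Bonferroni t.

These are the two non-set-machinery baselines: the exact two-sample
multivariate mean test, and the single-CpG two-sample t-test whose minimum
p-value, Bonferroni-multiplied by the number of CpGs, serves as the set
p-value.  The Bonferroni route ignores the correlation among CpGs and is
therefore conservative for correlated sets — increasingly so as the
correlation grows.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..containers import SetTestResult
from ._common import as_methylation_array, check_phenotype, drop_zero_variance

__all__ = ["hotelling_t2_test", "minp_bonferroni_t_test"]


def hotelling_t2_test(G, y) -> SetTestResult:
    """Two-sample Hotelling T-squared with pooled covariance and exact F.

    F = T^2 (n1 + n2 - p - 1) / (p (n1 + n2 - 2)) with (p, n1 + n2 - p - 1)
    degrees of freedom.
    """
    values, _ = as_methylation_array(G)
    y = check_phenotype(y, values.shape[0])
    g1, g2 = values[y == 1], values[y == 0]
    n1, n2 = len(g1), len(g2)
    p = values.shape[1]
    if min(n1, n2) < p + 1:
        raise ValueError(
            f"each group needs at least p + 1 = {p + 1} observations "
            f"(got {n1} cases, {n2} controls)"
        )
    d = g1.mean(axis=0) - g2.mean(axis=0)
    S = ((n1 - 1) * np.cov(g1, rowvar=False, ddof=1).reshape(p, p)
         + (n2 - 1) * np.cov(g2, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        raise ValueError(
            "pooled covariance is singular; reduce the CpG set "
            "(drop collinear or constant CpGs)"
        ) from None
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    f_stat = t2 * (n1 + n2 - p - 1) / (p * (n1 + n2 - 2))
    p_value = float(stats.f.sf(f_stat, p, n1 + n2 - p - 1))
    return SetTestResult(
        method="T2", statistic=t2, df=None, p_value=p_value,
        detail={"f_statistic": f_stat, "df1": p, "df2": n1 + n2 - p - 1},
    )


def minp_bonferroni_t_test(G, y, *, equal_var: bool = True) -> SetTestResult:
    """Per-CpG two-sample t-tests; set p = min(1, p * min_j p_j).

    Pooled-variance t by default (``equal_var=False`` for Welch).  The
    reported statistic is the t of the most significant CpG.
    """
    values, cpg_ids = as_methylation_array(G)
    y = check_phenotype(y, values.shape[0])
    values, cpg_ids = drop_zero_variance(values, cpg_ids, "min-p t-test")
    g1, g2 = values[y == 1], values[y == 0]
    t, pvals = stats.ttest_ind(g1, g2, axis=0, equal_var=equal_var)
    j = int(np.argmin(pvals))
    m = values.shape[1]
    return SetTestResult(
        method="MINP_T", statistic=float(t[j]), df=None,
        p_value=float(min(1.0, m * pvals[j])),
        detail={
            "top_cpg": cpg_ids[j],
            "min_p": float(pvals[j]),
            "n_tests": m,
            "equal_var": equal_var,
        },
    )
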