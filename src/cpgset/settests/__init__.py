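"""Set-based association tests for CpG methylation sets.

Seven tests share the signature ``test(G, y, ...) -> SetTestResult`` where
``G`` is a MethylationMatrix (or samples x CpGs array / DataFrame) and ``y``
a 0/1 phenotype vector; tests built on a logistic null model also accept an
optional covariate matrix.  ``run_method`` dispatches by the short method
names used across the package and the CLI:

====================  ==========================================
name                  test
====================  ==========================================
``pca``               PCA + k-df logistic LRT
``spca``              supervised PCA, permutation p-value
``kpca``              RBF kernel PCA + k-df logistic LRT
``skat``              variance-component score test (SKAT)
``sir``               sliced-inverse-regression dimension test
``t2``                two-sample Hotelling T-squared
``minp_t``            Bonferroni minimum-p two-sample t-test
====================  ==========================================
"""

from __future__ import annotations

from ..containers import MethylationMatrix, SetTestResult
from ..logistic import NullModel, fit_null_logistic, logistic_lrt
from .classical import hotelling_t2_test, minp_bonferroni_t_test
from .kernel import center_kernel, kpca_test, rbf_kernel
from .pca import pca_reduce, pca_test
from .sir import SirDecomposition, sir_decompose, sir_test
from .skat import skat_null, skat_statistic, skat_test
from .spca import spca_test

__all__ = [
    "MethylationMatrix",
    "SetTestResult",
    "NullModel",
    "fit_null_logistic",
    "logistic_lrt",
    "pca_reduce",
    "pca_test",
    "spca_test",
    "rbf_kernel",
    "center_kernel",
    "kpca_test",
    "skat_statistic",
    "skat_null",
    "skat_test",
    "SirDecomposition",
    "sir_decompose",
    "sir_test",
    "hotelling_t2_test",
    "minp_bonferroni_t_test",
    "METHODS",
    "run_method",
]

METHODS = ("pca", "spca", "kpca", "skat", "sir", "t2", "minp_t")


def run_method(name: str, G, y, covariates=None, *, seed: int = 0, **kwargs
               ) -> SetTestResult:
    """Dispatch a set test by short name (see module docstring for names).

    ``seed`` feeds the permutation null of SPCA and is ignored by the
    deterministic tests; extra keyword arguments go to the chosen test.
    """
    name = name.lower()
    if name == "pca":
        return pca_test(G, y, covariates, **kwargs)
    if name == "spca":
        return spca_test(G, y, covariates, seed=seed, **kwargs)
    if name == "kpca":
        return kpca_test(G, y, covariates, **kwargs)
    if name == "skat":
        return skat_test(G, y, covariates, **kwargs)
    if name == "sir":
        return sir_test(G, y, **kwargs)
    if name == "t2":
        return hotelling_t2_test(G, y, **kwargs)
    if name == "minp_t":
        return minp_bonferroni_t_test(G, y, **kwargs)
    raise KeyError(f"unknown method {name!r}; choose from {METHODS}")
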