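"""Sliced inverse regression set test.

SIR regresses the predictors on the response: the CpG matrix is
standardized to Z = Sigma_GG^{-1/2} (G - E G), the response range is cut
into H slices (the two outcome classes for a binary phenotype), and the
weighted between-slice covariance of the slice means of Z,

    M = sum_h p_h m_h m_h',

is eigendecomposed; its leading eigenvectors (mapped back to the original
scale) estimate the effective dimension-reduction directions.  The set test
is the classical dimension test of "no SIR directions": n times the sum of
the eigenvalues of M referred to chi-square with p (H - 1) degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..containers import SetTestResult
from ._common import as_methylation_array

__all__ = ["SirDecomposition", "sir_decompose", "sir_test"]


@dataclass
class SirDecomposition:
    slice_proportions: np.ndarray   # p_h, sums to 1
    slice_means: np.ndarray         # H x p standardized slice means m_h
    eigenvalues: np.ndarray         # nonincreasing, >= 0
    directions: np.ndarray          # p x p, columns on the original scale
    n_slices: int


def _inv_sqrt(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    top = vals.max()
    if top <= 0:
        raise ValueError("sample covariance of the CpG set is zero")
    if vals.min() < 1e-10 * top:
        # ridge-regularize a (near-)singular covariance
        cov = cov + (1e-8 * np.trace(cov) / cov.shape[0]) * np.eye(cov.shape[0])
        vals, vecs = np.linalg.eigh(cov)
    return (vecs / np.sqrt(vals)) @ vecs.T


def _slice_indicator(y: np.ndarray, n_slices: int) -> np.ndarray:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("response is constant; cannot form slices")
    if classes.size <= n_slices:
        return np.searchsorted(classes, y)
    # continuous response: quantile slicing
    edges = np.quantile(y, np.linspace(0, 1, n_slices + 1)[1:-1])
    return np.searchsorted(edges, y, side="right")


def sir_decompose(G, y, n_slices: int = 2) -> SirDecomposition:
    """Standardize, slice, and eigendecompose the between-slice covariance."""
    values, _ = as_methylation_array(G)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != values.shape[0]:
        raise ValueError("response length does not match the sample count")
    if n_slices < 2:
        raise ValueError("need at least two slices")
    slice_of = _slice_indicator(y, n_slices)
    labels = np.unique(slice_of)
    if labels.size < 2:
        raise ValueError("fewer than two nonempty slices")
    n, p = values.shape
    cov = np.cov(values, rowvar=False, ddof=1).reshape(p, p)
    W = _inv_sqrt(cov)
    Z = (values - values.mean(axis=0)) @ W
    props = np.array([(slice_of == h).mean() for h in labels])
    means = np.vstack([Z[slice_of == h].mean(axis=0) for h in labels])
    M = (means * props[:, None]).T @ means
    vals, vecs = np.linalg.eigh((M + M.T) / 2)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    vals = np.clip(vals, 0.0, None)
    return SirDecomposition(
        slice_proportions=props,
        slice_means=means,
        eigenvalues=vals,
        directions=W @ vecs,
        n_slices=int(labels.size),
    )


def sir_test(G, y, n_slices: int = 2) -> SetTestResult:
    """Dimension test of H0: no SIR directions.

    Statistic n * sum(eigenvalues), chi-square reference with p (H - 1)
    degrees of freedom; with a binary phenotype H = 2 and df = p.
    """
    values, _ = as_methylation_array(G)
    dec = sir_decompose(values, y, n_slices)
    n, p = values.shape
    stat = float(n * dec.eigenvalues.sum())
    df = p * (dec.n_slices - 1)
    return SetTestResult(
        method="SIR", statistic=stat, df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        detail={
            "eigenvalues": dec.eigenvalues.tolist(),
            "n_slices": dec.n_slices,
        },
    )
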