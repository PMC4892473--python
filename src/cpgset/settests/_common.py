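"""Shared input coercion for the set tests."""

from __future__ import annotations

import logging

import numpy as np

from ..containers import MethylationMatrix

logger = logging.getLogger("cpgset")


def as_methylation_array(G) -> tuple[np.ndarray, list[str]]:
    """Coerce a MethylationMatrix / DataFrame / array to (values, cpg_ids)."""
    if isinstance(G, MethylationMatrix):
        return G.values, list(G.cpg_ids)
    if hasattr(G, "to_numpy") and hasattr(G, "columns"):  # DataFrame
        return G.to_numpy(dtype=float), [str(c) for c in G.columns]
    arr = np.asarray(G, dtype=float)
    if arr.ndim != 2:
        raise ValueError("methylation input must be 2-d (samples x CpGs)")
    return arr, [f"cpg_{j + 1}" for j in range(arr.shape[1])]


def check_phenotype(y, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size != n:
        raise ValueError(f"phenotype length {y.size} does not match {n} samples")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("phenotype must be coded 0/1")
    if classes.size < 2:
        raise ValueError("phenotype contains a single class")
    return y


def drop_zero_variance(values: np.ndarray, cpg_ids: list[str], method: str
                       ) -> tuple[np.ndarray, list[str]]:
    sd = values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cpg_ids, keep) if not k]
        logger.warning("%s: dropping %d zero-variance CpG column(s): %s",
                       method, len(dropped), dropped)
        values = values[:, keep]
        cpg_ids = [c for c, k in zip(cpg_ids, keep) if k]
    if values.shape[1] == 0:
        raise ValueError(f"{method}: every CpG column is constant")
    return values, cpg_ids
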