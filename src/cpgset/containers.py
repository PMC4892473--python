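"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MethylationMatrix", "SetTestResult"]


@dataclass
class MethylationMatrix:
    """An n-samples x p-CpGs matrix of methylation beta-values.

    Beta-values are methylation proportions in [0, 1] (0 = unmethylated,
    1 = completely methylated), one column per CpG site.  This is the
    ``G`` matrix consumed by every set-based test.
    """

    values: np.ndarray
    cpg_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array (samples x CpGs)")
        n, p = self.values.shape
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.cpg_ids) != p:
            raise ValueError(f"{len(self.cpg_ids)} CpG ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if np.isnan(self.values).any():
            bad = np.argwhere(np.isnan(self.values))
            i, j = bad[0]
            raise ValueError(
                f"missing beta-values are not allowed; first at sample "
                f"{self.sample_ids[i]!r}, CpG {self.cpg_ids[j]!r} "
                f"({len(bad)} missing in total)"
            )
        if (self.values < 0).any() or (self.values > 1).any():
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            i, j = bad[0]
            raise ValueError(
                f"beta-values must lie in [0, 1]; found "
                f"{self.values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"CpG {self.cpg_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def zero_variance_columns(self, tol: float = 0.0) -> np.ndarray:
        """Indices of CpG columns with (numerically) zero variance."""
        sd = self.values.std(axis=0)
        return np.flatnonzero(sd <= tol)

    def subset(self, cpg_ids: Sequence[str]) -> "MethylationMatrix":
        """Column subset by CpG id, preserving the requested order."""
        index = {c: j for j, c in enumerate(self.cpg_ids)}
        missing = [c for c in cpg_ids if c not in index]
        if missing:
            raise KeyError(f"CpG ids not in matrix: {missing}")
        cols = [index[c] for c in cpg_ids]
        return MethylationMatrix(
            self.values[:, cols], [self.cpg_ids[j] for j in cols], list(self.sample_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MethylationMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(c) for c in frame.columns],
            [str(i) for i in frame.index],
        )

    @classmethod
    def from_values(cls, values: np.ndarray, prefix: str = "cg") -> "MethylationMatrix":
        """Wrap a bare array with autogenerated sample / CpG labels."""
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        return cls(
            values,
            [f"{prefix}{j:05d}" for j in range(1, p + 1)],
            [f"S{i:04d}" for i in range(1, n + 1)],
        )


@dataclass
class SetTestResult:
    """Outcome of one set-based association test on one CpG set.

    ``df`` is None for tests without a chi-square style degrees-of-freedom
    notion (permutation SPCA, SKAT's mixture null).  ``detail`` carries
    method-specific diagnostics (retained components, selected CpGs,
    eigenvalues, permutation counts, fallbacks).
    """

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    detail: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"{self.method}: non-finite statistic {self.statistic}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.method}: p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "df": None if self.df is None else int(self.df),
            "p_value": float(self.p_value),
            "detail": dict(self.detail),
        }
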