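"""Readers and writers: beta-value matrices, set definitions, results.

The matrix format models HM450-style beta-value exports: delimited text,
first column = sample ID, header row = CpG IDs, entries in [0, 1].  The
delimiter is auto-detected (tab or comma) unless given explicitly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, SetTestResult
from .simharness import SimulationSummary

logger = logging.getLogger("cpgset")

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_phenotype",
    "read_set_definitions",
    "write_results",
    "format_scientific",
]


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_beta_matrix(path, sep: str | None = None) -> MethylationMatrix:
    """Read a samples x CpGs beta-value matrix from delimited text.

    Raises on missing cells, non-numeric entries and values outside [0, 1],
    reporting the offending coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0,
                        float_precision="round_trip")
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no CpG columns found (malformed header?)")
    bad = frame.columns[~frame.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        for col in bad:
            rows = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()
                               & frame[col].notna()]
            if len(rows):
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r}, "
                    f"first at sample {rows[0]!r}"
                )
        frame[bad] = frame[bad].apply(pd.to_numeric)
    return MethylationMatrix.from_frame(frame)  # range/missing checks inside


def write_beta_matrix(matrix: MethylationMatrix, y, path, sep: str = "\t") -> None:
    """Write a simulated dataset: sample ID, phenotype y, then beta-values."""
    frame = matrix.to_frame()
    frame.insert(0, "y", np.asarray(y, dtype=int))
    frame.to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def read_phenotype(path, sep: str | None = None
                   ) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Read (y, sample_ids, covariates) from a phenotype table.

    Column layout: sample ID, ``y`` in {0, 1}, then optional covariate
    columns.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0)
    if "y" not in frame.columns:
        raise ValueError(f"{path}: phenotype file needs a 'y' column")
    y = frame["y"].to_numpy()
    if not np.isin(np.unique(y), (0, 1)).all():
        raise ValueError(f"{path}: phenotype must be coded 0/1")
    covars = frame.drop(columns="y")
    X = covars.to_numpy(dtype=float) if covars.shape[1] else None
    return y.astype(int), [str(s) for s in frame.index], X


def read_set_definitions(path, sep: str | None = None) -> dict[str, list[str]]:
    """Read CpG-set membership: two columns (set label, CpG ID).

    Membership lists keep file order and are de-duplicated; sets may
    overlap.  Empty sets are skipped with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path, sep), header=None,
                        comment="#", skip_blank_lines=True,
                        names=["set", "cpg"], dtype=str)
    sets: dict[str, list[str]] = {}
    for label, cpg in frame.itertuples(index=False):
        if pd.isna(cpg) or not str(cpg).strip():
            continue
        sets.setdefault(str(label).strip(), [])
        members = sets[str(label).strip()]
        cpg = str(cpg).strip()
        if cpg not in members:
            members.append(cpg)
    for label in [lb for lb, mem in sets.items() if not mem]:
        logger.warning("set %r is empty; skipping", label)
        del sets[label]
    return sets


def format_scientific(p: float) -> str:
    """Display formatting for p-values, e.g. 4.06e-05 -> '4.06E-05'."""
    return f"{p:.2E}"


def _record(item, set_label: str | None) -> dict:
    if isinstance(item, SetTestResult):
        rec = item.to_dict()
    elif isinstance(item, SimulationSummary):
        rec = item.to_dict()
    elif isinstance(item, Mapping):
        rec = dict(item)
    else:
        raise TypeError(f"cannot serialize result of type {type(item)!r}")
    if set_label is not None and "set" not in rec:
        rec = {"set": set_label, **rec}
    return rec


def write_results(
    results: Iterable,
    path,
    fmt: str = "tsv",
    *,
    set_labels: Sequence[str] | None = None,
    metadata: Mapping | None = None,
) -> None:
    """Write SetTestResult / SimulationSummary rows as TSV or JSON.

    TSV output adds a ``p_display`` column in scientific notation; JSON
    output embeds ``metadata`` (seed, config, version) alongside the rows.
    """
    results = list(results)
    labels = list(set_labels) if set_labels is not None else [None] * len(results)
    if len(labels) != len(results):
        raise ValueError("set_labels length does not match results")
    records = [_record(r, lb) for r, lb in zip(results, labels)]
    path = Path(path)
    if fmt == "json":
        payload = {"metadata": dict(metadata or {}), "results": records}
        path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unknown output format {fmt!r} (use 'tsv' or 'json')")
    for rec in records:
        rec.pop("detail", None)
        for key in ("p_value", "rejection_rate"):
            if key in rec and rec[key] is not None and np.isfinite(rec[key]):
                rec["p_display" if key == "p_value" else "rate_display"] = (
                    format_scientific(rec[key]))
    frame = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["set", "method", "statistic", "df", "p_value", "p_display"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
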