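"""Built-in simulation scenario library and scenario-file loading.

Two families of benchmark scenarios ship with the package:

* **Virtual CpG sets** ("1.1" ... "2.7"): 10 CpGs, 1000 cases + 1000
  controls, exchangeable pairwise correlation r in {0.2, 0.4, 0.6, 0.8}.
  Scenario family 1 draws all CpGs from a common beta marginal (mean
  0.2/0.4/0.6/0.8, default 0.6); family 2 uses ten distinct marginal means
  (0.2, 0.2, 0.3, 0.4, 0.5, 0.5, 0.6, 0.7, 0.8, 0.8).  Causal-CpG
  locations and effect-size grids differ per scenario (see ``EFFECT_GRIDS``).

* **Real-template CpG sets** ("PTPRD", "MLH1"): 6 and 9 CpGs whose target
  correlation matrices are the sample correlation matrices of the PTPRD and
  MLH1 gene-region CpGs in an Illumina 450K rheumatoid-arthritis dataset;
  50 cases + 50 controls; the first CpG of the set is causal under the
  alternative with effect 4.0 or 5.0.

Custom scenarios can be read from YAML/JSON via ``load_scenario_file``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import yaml

from .datagen import (
    BetaMarginalSpec,
    CorrelationTarget,
    DiseaseModelSpec,
    ScenarioSpec,
)

__all__ = [
    "R1_PTPRD",
    "R2_MLH1",
    "EFFECT_GRIDS",
    "CORRELATION_GRID",
    "SCENARIO2_MEANS",
    "list_scenarios",
    "get_scenario",
    "load_scenario_file",
]

DEFAULT_PRECISION = 10.0
CORRELATION_GRID = (0.2, 0.4, 0.6, 0.8)
SCENARIO2_MEANS = (0.2, 0.2, 0.3, 0.4, 0.5, 0.5, 0.6, 0.7, 0.8, 0.8)


def _from_lower(p: int, rows: Sequence[Sequence[float]]) -> np.ndarray:
    m = np.eye(p)
    for i, row in enumerate(rows, start=1):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return m


# Sample Pearson correlation matrix of 6 CpGs within 1 kb of PTPRD
# (cg08719869, cg09371281, cg09781601, cg13723825, cg14080967, cg14458619)
# from 450K whole-blood data (GEO accession GSE42861).
R1_PTPRD = _from_lower(6, [
    [0.264],
    [0.469, 0.257],
    [0.778, 0.224, 0.458],
    [0.890, 0.248, 0.410, 0.819],
    [0.374, 0.894, 0.286, 0.315, 0.364],
])

# Sample Pearson correlation matrix of 9 CpGs within 1 kb of MLH1
# (cg02103401, cg04726821, cg04841293, cg05670953, cg10990993, cg11291081,
#  cg18320188, cg21109167, cg24607398), same dataset.
R2_MLH1 = _from_lower(9, [
    [0.432],
    [0.138, 0.303],
    [0.331, 0.709, 0.292],
    [0.679, 0.576, 0.146, 0.440],
    [0.272, 0.600, 0.268, 0.660, 0.308],
    [0.311, 0.421, 0.538, 0.518, 0.307, 0.443],
    [0.113, 0.585, 0.453, 0.668, 0.262, 0.417, 0.449],
    [0.610, 0.498, 0.065, 0.378, 0.710, 0.299, 0.210, 0.160],
])

# (number of causal CpGs, 1-based causal locations, effect-size grid)
_ONE_CAUSAL_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
_TWO_CAUSAL_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)
_VIRTUAL = {
    "1.1": ((), ()),
    "1.2": ((1,), _ONE_CAUSAL_GRID),
    "1.3": ((1, 2), _TWO_CAUSAL_GRID),
    "2.1": ((), ()),
    "2.2": ((1,), _ONE_CAUSAL_GRID),
    "2.3": ((5,), _ONE_CAUSAL_GRID),
    "2.4": ((10,), _ONE_CAUSAL_GRID),
    "2.5": ((1, 5), _TWO_CAUSAL_GRID),
    "2.6": ((1, 10), _TWO_CAUSAL_GRID),
    "2.7": ((5, 10), _TWO_CAUSAL_GRID),
}
_REAL = {
    "PTPRD": (R1_PTPRD, (4.0, 5.0)),
    "MLH1": (R2_MLH1, (4.0, 5.0)),
}

#: label -> grid of admissible per-CpG effect sizes under the alternative
EFFECT_GRIDS = {label: grid for label, (_, grid) in _VIRTUAL.items()} | {
    label: grid for label, (_, grid) in _REAL.items()
}


def list_scenarios() -> list[dict]:
    """Summaries of the built-in scenario library."""
    rows = []
    for label, (causal, grid) in _VIRTUAL.items():
        rows.append({
            "label": label,
            "p": 10,
            "n_cases": 1000, "n_controls": 1000,
            "marginal_means": "0.6 (configurable)" if label.startswith("1")
            else "/".join(str(m) for m in SCENARIO2_MEANS),
            "correlation": "exchangeable r in " + "/".join(map(str, CORRELATION_GRID)),
            "causal_locations": causal,
            "effect_grid": grid,
        })
    for label, (R, grid) in _REAL.items():
        rows.append({
            "label": label,
            "p": R.shape[0],
            "n_cases": 50, "n_controls": 50,
            "marginal_means": "0.5 (configurable)",
            "correlation": f"printed {R.shape[0]}x{R.shape[0]} template matrix",
            "causal_locations": (1,) if grid else (),
            "effect_grid": grid,
        })
    return rows


def get_scenario(
    label: str,
    *,
    r: float | None = None,
    effect: float | Sequence[float] | None = None,
    mean: float = 0.6,
    precision: float = DEFAULT_PRECISION,
    template_mean: float = 0.5,
    null: bool = False,
) -> ScenarioSpec:
    """Build a built-in scenario by label.

    For the virtual scenarios ``r`` selects the exchangeable correlation
    (required) and ``mean`` sets the common marginal mean for family 1.
    ``effect`` gives the causal effect size(s) (scalar applied to every
    causal CpG, or one value per causal CpG); ``null=True`` forces C = 0.
    The disease-model intercept is centered so that expected prevalence is
    about one half, matching the balanced quotas.
    """
    if label in _VIRTUAL:
        if r is None:
            raise ValueError(f"virtual scenario {label!r} needs the correlation r")
        causal, grid = _VIRTUAL[label]
        if label.startswith("1"):
            marginals = [BetaMarginalSpec(mean, precision)] * 10
        else:
            marginals = [BetaMarginalSpec(m, precision) for m in SCENARIO2_MEANS]
        correlation = CorrelationTarget.exchangeable(r, 10)
        n_cases = n_controls = 1000
        suffix = f" (r={r})"
    elif label in _REAL:
        R, grid = _REAL[label]
        causal = (1,) if grid else ()
        marginals = [BetaMarginalSpec(template_mean, precision)] * R.shape[0]
        correlation = CorrelationTarget(R)
        n_cases = n_controls = 50
        suffix = ""
    else:
        known = sorted(_VIRTUAL) + sorted(_REAL)
        raise KeyError(f"unknown scenario {label!r}; built-ins: {known}")

    if null or not causal:
        disease = DiseaseModelSpec()
        causal = ()
    else:
        if effect is None:
            raise ValueError(
                f"scenario {label!r} is an alternative scenario; pass effect= "
                f"(grid: {grid}) or null=True"
            )
        effects = (
            tuple(float(effect) for _ in causal)
            if np.isscalar(effect) else tuple(float(b) for b in effect)
        )
        if len(effects) != len(causal):
            raise ValueError(
                f"scenario {label!r} has {len(causal)} causal CpGs; "
                f"got {len(effects)} effects"
            )
        disease = DiseaseModelSpec(causal_indices=causal, effects=effects)
    spec = ScenarioSpec(marginals, correlation, disease, n_cases, n_controls,
                        label=label + suffix)
    if causal:
        spec.disease = DiseaseModelSpec(
            intercept=spec.centered_intercept(),
            causal_indices=disease.causal_indices,
            effects=disease.effects,
        )
    return spec


def _parse_correlation(entry, p_hint: int | None) -> CorrelationTarget:
    if isinstance(entry, dict):
        r = float(entry["exchangeable"])
        p = int(entry.get("p", p_hint or 0))
        if p < 2:
            raise ValueError("exchangeable correlation needs 'p' >= 2")
        return CorrelationTarget.exchangeable(r, p)
    return CorrelationTarget(np.asarray(entry, dtype=float))


def load_scenario_file(path) -> ScenarioSpec:
    """Read a ScenarioSpec from a YAML or JSON scenario file.

    Expected keys: ``marginals`` (list of {mean, precision}), ``correlation``
    (dense matrix or {exchangeable: r, p: p}), ``disease`` ({intercept,
    causal_indices, effects}), ``n_cases``, ``n_controls``, optional
    ``label``.  JSON is a subset of YAML, so one loader covers both.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    marginals = [
        BetaMarginalSpec(float(m["mean"]), float(m.get("precision", DEFAULT_PRECISION)))
        for m in cfg["marginals"]
    ]
    correlation = _parse_correlation(cfg["correlation"], len(marginals))
    d = cfg.get("disease", {}) or {}
    disease = DiseaseModelSpec(
        intercept=float(d.get("intercept", 0.0)),
        causal_indices=tuple(d.get("causal_indices", ())),
        effects=tuple(d.get("effects", ())),
    )
    return ScenarioSpec(
        marginals, correlation, disease,
        int(cfg["n_cases"]), int(cfg["n_controls"]),
        label=str(cfg.get("label", "custom")),
    )
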