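"""Monte Carlo engine for empirical type I error and power estimation.

Each replication t draws one case/control dataset with seed
``base_seed + t`` (so any single replication is reproducible in isolation
and the partitioning of work across processes cannot change results), runs
every requested set test on the same dataset (common random numbers across
methods), and records whether each method's p-value falls at or below the
significance level.  Under a null scenario (no causal CpGs) the rejection
rate estimates the type I error; under an alternative it estimates power.

Method errors inside a replication are counted separately, never coerced to
non-rejections; a summary with more than 1% errored replications is flagged
invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datagen import ScenarioSpec, sample_case_control
from .scenarios import CORRELATION_GRID, get_scenario
from .settests import METHODS, run_method

logger = logging.getLogger("cpgset")

__all__ = ["SimulationSummary", "estimate_rejection_rate", "type1_table", "power_curve"]


@dataclass
class SimulationSummary:
    """Empirical rejection rate of one method under one scenario."""

    scenario_label: str
    method: str
    alpha: float
    n_replications: int
    n_rejections: int
    n_errors: int
    base_seed: int
    detail: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return self.n_replications - self.n_errors

    @property
    def rejection_rate(self) -> float:
        return self.n_rejections / self.n_valid if self.n_valid else float("nan")

    @property
    def mc_standard_error(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1 - r) / self.n_valid)) if self.n_valid else float("nan")

    @property
    def valid(self) -> bool:
        return self.n_errors <= 0.01 * self.n_replications

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_label,
            "method": self.method,
            "alpha": self.alpha,
            "n_replications": self.n_replications,
            "n_rejections": self.n_rejections,
            "n_errors": self.n_errors,
            "rejection_rate": self.rejection_rate,
            "mc_standard_error": self.mc_standard_error,
            "base_seed": self.base_seed,
            "valid": self.valid,
        }


def _one_replication(scenario: ScenarioSpec, methods: Sequence[str], alpha: float,
                     seed: int, method_kwargs: dict) -> dict[str, int]:
    """Returns per-method outcome: 1 reject, 0 accept, -1 error."""
    G, y = sample_case_control(scenario, seed)
    out: dict[str, int] = {}
    for m in methods:
        try:
            res = run_method(m, G, y, seed=seed, **method_kwargs.get(m, {}))
            out[m] = int(res.p_value <= alpha)
        except Exception as exc:  # noqa: BLE001 — logged, counted, not coerced
            logger.warning("replication seed=%d method=%s failed: %s", seed, m, exc)
            out[m] = -1
    return out


def estimate_rejection_rate(
    scenario: ScenarioSpec,
    methods: Sequence[str],
    n_replications: int,
    alpha: float = 0.05,
    base_seed: int = 0,
    *,
    method_kwargs: dict | None = None,
    n_jobs: int = 1,
) -> list[SimulationSummary]:
    """Empirical rejection rate of each method over ``n_replications``.

    Replication t uses dataset seed ``base_seed + t`` (t = 1..R); results
    are invariant to ``n_jobs``.  ``method_kwargs`` maps method name to
    extra keyword arguments (e.g. ``{"spca": {"n_permutations": 199}}``).
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise KeyError(f"unknown methods {unknown}; choose from {METHODS}")
    method_kwargs = method_kwargs or {}
    scenario.copula()  # calibrate once, before any fork
    seeds = [base_seed + t for t in range(1, n_replications + 1)]
    if n_jobs == 1:
        outcomes = [_one_replication(scenario, methods, alpha, s, method_kwargs)
                    for s in seeds]
    else:
        outcomes = Parallel(n_jobs=n_jobs)(
            delayed(_one_replication)(scenario, methods, alpha, s, method_kwargs)
            for s in seeds
        )
    summaries = []
    for m in methods:
        flags = [o[m] for o in outcomes]
        summaries.append(SimulationSummary(
            scenario_label=scenario.label,
            method=m,
            alpha=alpha,
            n_replications=n_replications,
            n_rejections=sum(f == 1 for f in flags),
            n_errors=sum(f == -1 for f in flags),
            base_seed=base_seed,
        ))
    for s in summaries:
        if not s.valid:
            logger.warning("summary %s/%s: %d errored replications (> 1%%), "
                           "flagged invalid", s.scenario_label, s.method, s.n_errors)
    return summaries


def type1_table(
    scenarios: Sequence[ScenarioSpec],
    methods: Sequence[str],
    n_replications: int,
    alpha: float = 0.05,
    base_seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Rows = scenarios, columns = methods, entries = empirical type I error."""
    rows = {}
    for sc in scenarios:
        summaries = estimate_rejection_rate(
            sc, methods, n_replications, alpha, base_seed, **kwargs
        )
        rows[sc.label] = {s.method: s.rejection_rate for s in summaries}
    return pd.DataFrame.from_dict(rows, orient="index")[list(methods)]


def null_grid(label: str = "1.1", *, mean: float = 0.6,
              correlations: Sequence[float] = CORRELATION_GRID) -> list[ScenarioSpec]:
    """Null scenarios of a virtual family across the correlation grid."""
    return [get_scenario(label, r=r, mean=mean, null=True) for r in correlations]


def power_curve(
    scenario_label: str,
    effect_grid: Sequence[float],
    methods: Sequence[str],
    n_replications: int,
    alpha: float = 0.05,
    base_seed: int = 0,
    *,
    r: float | None = None,
    mean: float = 0.6,
    method_kwargs: dict | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Power per (effect size, method) for one built-in scenario family.

    Sweeps the causal effect size over ``effect_grid`` at fixed correlation;
    an effect of 0 reduces to the null scenario, so the corresponding row
    estimates the type I error.  Returns a tidy frame with one row per
    (effect, method) including the Monte Carlo standard error.
    """
    records = []
    for beta in effect_grid:
        sc = (get_scenario(scenario_label, r=r, mean=mean, null=True)
              if beta == 0 else
              get_scenario(scenario_label, r=r, mean=mean, effect=float(beta)))
        for s in estimate_rejection_rate(sc, methods, n_replications, alpha,
                                         base_seed, method_kwargs=method_kwargs,
                                         n_jobs=n_jobs):
            rec = s.to_dict()
            rec["effect"] = float(beta)
            records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df[["scenario", "effect", "method", "rejection_rate",
               "mc_standard_error", "n_replications", "n_errors", "base_seed"]]
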