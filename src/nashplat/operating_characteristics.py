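"""Operating characteristics: aggregate replicates, sweep scenario grids.

The central quantity is the success probability -- the fraction of treatment
cohorts declared superior to control at any analysis. Under a null treatment
effect it is the design's type I error; under an efficacious treatment it is
power. Because every cohort in a replicate shares one treatment-effect
scenario, cohorts are exchangeable and success is pooled over all cohorts of
all replicates (max_cohorts x n_sims evaluations); the Monte-Carlo standard
error reflects that pooled count. Durations and enrollment are averaged per
replicate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .trial_engine import PlatformConfig, PlatformResult, run_replicates

__all__ = [
    "OCSummary",
    "OC_COLUMNS",
    "summarize",
    "run_scenario",
    "scenario_grid",
    "write_oc_table",
    "read_oc_table",
]


@dataclass(frozen=True)
class OCSummary:
    """Aggregated operating characteristics for one scenario."""

    # scenario descriptors
    e1_rate: float
    e2_rate: float
    rho: float
    cohort_size: int
    sharing_mode: str
    evidence_level: int
    # operating characteristics
    success_prob: float
    success_prob_se: float
    futility_prob: float
    avg_duration_weeks: float
    avg_total_enrolled: float
    participants_saved: float
    cum_go_ia1: float
    cum_stop_ia1: float
    cum_decision_ia1: float
    cum_go_ia2: float
    cum_stop_ia2: float
    cum_decision_ia2: float
    cum_decision_ia1_se: float
    cum_decision_ia2_se: float
    n_sims: int
    n_cohort_evaluations: int

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


OC_COLUMNS = [f.name for f in fields(OCSummary)]


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n)) if n > 0 else float("nan")


def summarize(results: list[PlatformResult], config: PlatformConfig) -> OCSummary:
    """Pool cohort decisions across replicates into one scenario summary."""
    if not results:
        raise ValueError("cannot summarize an empty result list")
    records = [rec for res in results for rec in res.cohorts]
    n_eval = len(records)
    go = np.array([rec.decision == "GO" for rec in records])
    ia = np.array([rec.analysis_index for rec in records])
    success = float(go.mean())
    cum_go_ia1 = float((go & (ia == 1)).mean())
    cum_stop_ia1 = float((~go & (ia == 1)).mean())
    cum_go_ia2 = float((go & (ia <= 2)).mean())
    cum_stop_ia2 = float((~go & (ia <= 2)).mean())
    durations = np.array([res.platform_duration_weeks for res in results], dtype=float)
    enrolled = np.array([res.total_enrolled for res in results], dtype=float)
    planned = config.max_cohorts * config.cohort_size
    return OCSummary(
        e1_rate=config.trt_rates[0],
        e2_rate=config.trt_rates[1],
        rho=config.rho,
        cohort_size=config.cohort_size,
        sharing_mode=config.sharing_mode,
        evidence_level=config.rules.evidence_level_required,
        success_prob=success,
        success_prob_se=_binom_se(success, n_eval),
        futility_prob=1.0 - success,
        avg_duration_weeks=float(durations.mean()),
        avg_total_enrolled=float(enrolled.mean()),
        participants_saved=planned - float(enrolled.mean()),
        cum_go_ia1=cum_go_ia1,
        cum_stop_ia1=cum_stop_ia1,
        cum_decision_ia1=cum_go_ia1 + cum_stop_ia1,
        cum_go_ia2=cum_go_ia2,
        cum_stop_ia2=cum_stop_ia2,
        cum_decision_ia2=cum_go_ia2 + cum_stop_ia2,
        cum_decision_ia1_se=_binom_se(cum_go_ia1 + cum_stop_ia1, n_eval),
        cum_decision_ia2_se=_binom_se(cum_go_ia2 + cum_stop_ia2, n_eval),
        n_sims=len(results),
        n_cohort_evaluations=n_eval,
    )


def run_scenario(
    config: PlatformConfig,
    n_sims: int | None = None,
    seed: int | None = None,
) -> OCSummary:
    """Simulate one scenario end to end and summarize it."""
    return summarize(run_replicates(config, n_sims=n_sims, seed=seed), config)


def scenario_grid(
    base: PlatformConfig,
    e1_rates: list[float],
    e2_rates: list[float],
    rhos: list[float],
    sizes: list[int],
    modes: list[str],
    levels: list[int] | None = None,
) -> list[PlatformConfig]:
    """Cartesian product of scenario axes with deterministic per-scenario seeds.

    Seeds are derived counter-style from the base seed, so adding axes or
    running scenarios in parallel cannot change any scenario's stream.
    """
    axes = {
        "e1_rates": e1_rates,
        "e2_rates": e2_rates,
        "rhos": rhos,
        "sizes": sizes,
        "modes": modes,
        "levels": levels if levels is not None else [base.rules.evidence_level_required],
    }
    cleaned = {}
    for name, values in axes.items():
        if not values:
            raise ValueError(f"axis {name!r} must be non-empty")
        unique = list(dict.fromkeys(values))
        if len(unique) < len(values):
            warnings.warn(f"duplicate values in axis {name!r} were deduplicated")
        cleaned[name] = unique
    configs = []
    for i, (r1, r2, rho, size, mode, level) in enumerate(
        itertools.product(*cleaned.values())
    ):
        rules = base.rules
        if level != rules.evidence_level_required:
            from dataclasses import replace as _replace

            rules = _replace(rules, evidence_level_required=level)
        configs.append(
            base.with_overrides(
                trt_rates=(r1, r2),
                rho=rho,
                cohort_size=size,
                sharing_mode=mode,
                rules=rules,
                seed=(base.seed * 1_000_003 + i) % (2**31),
            )
        )
    return configs


def write_oc_table(summaries: list[OCSummary], path) -> None:
    """One CSV row per scenario, fixed column order, full float precision."""
    frame = pd.DataFrame([s.to_dict() for s in summaries], columns=OC_COLUMNS)
    frame.to_csv(path, index=False)


def read_oc_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
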