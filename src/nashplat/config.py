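"""Configuration files, validation and run manifests.

Config files are YAML (JSON is a YAML subset) whose top-level keys mirror
:class:`~nashplat.trial_engine.PlatformConfig` field names; absent keys take
the design defaults, unknown keys are rejected. The decision rules live under
a ``decision_rules`` block::

    decision_rules:
      evidence_level_required: 3
      efficacy_combiner: any
      endpoints:
        - levels: [{delta: 0.0, gamma: 0.95}, {delta: 0.30, gamma: 0.85},
                   {delta: 0.40, gamma: 0.60}]
          futility: {delta: 0.25, gamma_ia1: 0.20, gamma_ia2: 0.30}
        - levels: [{delta: 0.0, gamma: 0.95}, {delta: 0.175, gamma: 0.85},
                   {delta: 0.25, gamma: 0.60}]
          futility: {delta: 0.10, gamma_ia1: 0.20, gamma_ia2: 0.30}

A :class:`RunManifest` snapshots the resolved config, seed and per-scenario
seed table so any output can be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import yaml

from .decision_rules import DecisionRuleSet, EvidenceLevel, FutilityGate
from .trial_engine import PlatformConfig

__all__ = [
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "save_config",
    "RunManifest",
]

_SIMPLE_KEYS = {
    "n_initial_cohorts",
    "max_cohorts",
    "cohort_entry_interval_weeks",
    "accrual_per_week",
    "outcome_lag_weeks",
    "cohort_size",
    "interim_fractions",
    "sharing_mode",
    "soc_rates",
    "trt_rates",
    "rho",
    "time_trend_per_week",
    "n_sims",
    "seed",
}


def _rules_from_dict(block: dict) -> DecisionRuleSet:
    known = {"evidence_level_required", "efficacy_combiner", "endpoints"}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown decision_rules keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "evidence_level_required" in block:
        kwargs["evidence_level_required"] = int(block["evidence_level_required"])
    if "efficacy_combiner" in block:
        kwargs["efficacy_combiner"] = str(block["efficacy_combiner"])
    if "endpoints" in block:
        levels = []
        futility = []
        for k, endpoint in enumerate(block["endpoints"], start=1):
            extra = set(endpoint) - {"levels", "futility"}
            if extra:
                raise ValueError(
                    f"unknown keys in decision_rules endpoint {k}: {sorted(extra)}"
                )
            levels.append(
                tuple(
                    EvidenceLevel(float(lv["delta"]), float(lv["gamma"]))
                    for lv in endpoint["levels"]
                )
            )
            fut = endpoint["futility"]
            gammas = []
            i = 1
            while f"gamma_ia{i}" in fut:
                gammas.append(float(fut[f"gamma_ia{i}"]))
                i += 1
            if not gammas:
                raise ValueError(
                    f"endpoint {k} futility block needs gamma_ia1, gamma_ia2, ..."
                )
            futility.append(FutilityGate(float(fut["delta"]), tuple(gammas)))
        kwargs["levels"] = tuple(levels)
        kwargs["futility"] = tuple(futility)
    return DecisionRuleSet(**kwargs)


def _rules_to_dict(rules: DecisionRuleSet) -> dict:
    endpoints = []
    for levels, gate in zip(rules.levels, rules.futility):
        fut = {"delta": gate.delta}
        for i, g in enumerate(gate.gamma_by_analysis, start=1):
            fut[f"gamma_ia{i}"] = g
        endpoints.append(
            {
                "levels": [{"delta": lv.delta, "gamma": lv.gamma} for lv in levels],
                "futility": fut,
            }
        )
    return {
        "evidence_level_required": rules.evidence_level_required,
        "efficacy_combiner": rules.efficacy_combiner,
        "endpoints": endpoints,
    }


def config_from_dict(raw: dict) -> PlatformConfig:
    """Build a validated PlatformConfig from a plain dict (defaults applied)."""
    unknown = set(raw) - _SIMPLE_KEYS - {"decision_rules"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: raw[k] for k in _SIMPLE_KEYS if k in raw}
    for key in ("interim_fractions", "soc_rates", "trt_rates"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "decision_rules" in raw:
        kwargs["rules"] = _rules_from_dict(raw["decision_rules"] or {})
    return PlatformConfig(**kwargs)


def config_to_dict(config: PlatformConfig) -> dict:
    """Round-trippable plain-dict form of a config."""
    out = {}
    for f in dataclasses.fields(config):
        if f.name == "rules":
            continue
        value = getattr(config, f.name)
        out[f.name] = list(value) if isinstance(value, tuple) else value
    out["decision_rules"] = _rules_to_dict(config.rules)
    return out


def load_config(path) -> PlatformConfig:
    """Load a YAML/JSON config file; an empty file yields the full defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(raw)


def save_config(config: PlatformConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def _code_version() -> str:
    try:
        return metadata.version("nashplat")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass(frozen=True)
class RunManifest:
    """Snapshot sufficient to reproduce a run bit-exactly."""

    config: dict
    seed: int
    scenario_seeds: dict = field(default_factory=dict)
    code_version: str = field(default_factory=_code_version)
    created_utc: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    @classmethod
    def for_run(
        cls, config: PlatformConfig, scenario_seeds: dict | None = None
    ) -> "RunManifest":
        return cls(
            config=config_to_dict(config),
            seed=config.seed,
            scenario_seeds=scenario_seeds or {},
        )

    def resolved_config(self) -> PlatformConfig:
        return config_from_dict(self.config)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)
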