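"""Multi-level Bayesian efficacy/futility gates for the two NASH endpoints.

Efficacy for a single endpoint is established by a conjunction of evidence
levels ``(delta_l, gamma_l)``: the posterior probability that the treatment
response rate exceeds the control rate by more than ``delta_l`` must be
strictly above ``gamma_l`` for every level up to the required one. The
default levels are

* endpoint 1 (NASH resolution):     (0, 0.95), (0.30, 0.85), (0.40, 0.60)
* endpoint 2 (fibrosis improvement): (0, 0.95), (0.175, 0.85), (0.25, 0.60)

applied identically at every analysis. A cohort graduates (GO) as soon as one
endpoint is efficacious (the FDA "OR" rule). At an interim it is dropped
(STOP) only if the futility gate fires on *both* endpoints: the posterior
probability of an advantage of at least 25 percentage points (endpoint 1) or
10 points (endpoint 2) is below 0.20 at the first interim and 0.30 at the
second. At the final analysis there is no futility gate -- failing efficacy
is futility.

Efficacy takes precedence when both raw conditions hold; the parameterization
is expected to preclude the overlap, and :func:`find_go_stop_overlap` can
scan a data grid to verify that for a given sample size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .bayes_posterior import ArmCounts, BetaPosterior, prob_exceeds_by, update

__all__ = [
    "EvidenceLevel",
    "FutilityGate",
    "DecisionRuleSet",
    "Decision",
    "GO",
    "STOP",
    "CONTINUE",
    "endpoint_efficacy",
    "endpoint_futility",
    "evaluate_cohort",
    "find_go_stop_overlap",
]

GO = "GO"
STOP = "STOP"
CONTINUE = "CONTINUE"

FLAT_PRIOR = BetaPosterior(1.0, 1.0)


@dataclass(frozen=True)
class EvidenceLevel:
    """One efficacy gate: margin delta with required confidence gamma."""

    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta={self.delta!r} outside [0, 1]")
        # gamma = 1 is legal: with a strict comparison it disables the gate
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma={self.gamma!r} outside (0, 1]")


@dataclass(frozen=True)
class FutilityGate:
    """Interim futility rule: stop evidence below gamma for a delta advantage.

    ``gamma_by_analysis[i]`` is the threshold at interim ``i + 1``; there is
    deliberately no entry for the final analysis.
    """

    delta: float
    gamma_by_analysis: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"futility delta={self.delta!r} outside [0, 1]")
        for g in self.gamma_by_analysis:
            if not 0.0 <= g < 1.0:
                raise ValueError(f"futility gamma={g!r} outside [0, 1)")

    def gamma(self, analysis_index: int) -> float:
        if not 1 <= analysis_index <= len(self.gamma_by_analysis):
            raise ValueError(
                f"no futility gate at analysis {analysis_index}; gates exist "
                f"for interims 1..{len(self.gamma_by_analysis)}"
            )
        return self.gamma_by_analysis[analysis_index - 1]


def _default_levels_e1() -> tuple[EvidenceLevel, ...]:
    return (
        EvidenceLevel(0.0, 0.95),
        EvidenceLevel(0.30, 0.85),
        EvidenceLevel(0.40, 0.60),
    )


def _default_levels_e2() -> tuple[EvidenceLevel, ...]:
    return (
        EvidenceLevel(0.0, 0.95),
        EvidenceLevel(0.175, 0.85),
        EvidenceLevel(0.25, 0.60),
    )


@dataclass(frozen=True)
class DecisionRuleSet:
    """Per-endpoint evidence levels and futility gates plus the combiners.

    ``evidence_level_required`` counts conjunctive levels (hierarchical: level
    2 includes level 1). ``efficacy_combiner`` is "any" for the FDA OR rule
    (default) or "all" for the EMA AND rule; futility always combines with
    "all" (both endpoints must look futile to drop at an interim).
    """

    levels: tuple[tuple[EvidenceLevel, ...], ...] = field(
        default_factory=lambda: (_default_levels_e1(), _default_levels_e2())
    )
    futility: tuple[FutilityGate, ...] = field(
        default_factory=lambda: (
            FutilityGate(0.25, (0.20, 0.30)),
            FutilityGate(0.10, (0.20, 0.30)),
        )
    )
    evidence_level_required: int = 3
    efficacy_combiner: str = "any"
    futility_combiner: str = "all"
    prior: BetaPosterior = FLAT_PRIOR

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.futility):
            raise ValueError("levels and futility must cover the same endpoints")
        for k, endpoint_levels in enumerate(self.levels, start=1):
            deltas = [lv.delta for lv in endpoint_levels]
            gammas = [lv.gamma for lv in endpoint_levels]
            if any(d2 <= d1 for d1, d2 in itertools.pairwise(deltas)):
                raise ValueError(
                    f"endpoint {k}: margins must strictly increase, got {deltas}"
                )
            if any(g2 >= g1 for g1, g2 in itertools.pairwise(gammas)):
                raise ValueError(
                    f"endpoint {k}: confidences must strictly decrease, "
                    f"got {gammas}"
                )
        n_levels = min(len(endpoint) for endpoint in self.levels)
        if not 1 <= self.evidence_level_required <= n_levels:
            raise ValueError(
                f"evidence_level_required={self.evidence_level_required!r} "
                f"outside 1..{n_levels}"
            )
        if self.efficacy_combiner not in ("any", "all"):
            raise ValueError(f"unknown efficacy_combiner {self.efficacy_combiner!r}")
        if self.futility_combiner != "all":
            raise ValueError("futility_combiner must be 'all'")

    @property
    def n_endpoints(self) -> int:
        return len(self.levels)

    @property
    def n_interims(self) -> int:
        return len(self.futility[0].gamma_by_analysis)

    @classmethod
    def default(cls) -> "DecisionRuleSet":
        return cls()


@dataclass(frozen=True)
class Decision:
    """Outcome of one cohort analysis with the probabilities that drove it.

    ``efficacy_probs[k][l]`` is P(pi_E > pi_S + delta_l) for endpoint k;
    ``futility_probs[k]`` is the corresponding futility-gate probability (None
    where not evaluated -- futility is only computed when efficacy failed at
    an interim). CONTINUE is never returned at the final analysis.
    """

    verdict: str
    efficacy_probs: tuple[tuple[float, ...], ...]
    futility_probs: tuple[float | None, ...]


def endpoint_efficacy(
    post_E: BetaPosterior,
    post_S: BetaPosterior,
    levels: tuple[EvidenceLevel, ...],
    required: int,
) -> bool:
    """True iff every level l <= required clears its confidence threshold."""
    if not 1 <= required <= len(levels):
        raise ValueError(f"required={required!r} outside 1..{len(levels)}")
    return all(
        prob_exceeds_by(post_E, post_S, lv.delta) > lv.gamma
        for lv in levels[:required]
    )


def endpoint_futility(
    post_E: BetaPosterior,
    post_S: BetaPosterior,
    gate: FutilityGate,
    analysis_index: int,
) -> bool:
    """True iff evidence for a delta_F advantage falls below the interim bar."""
    gamma = gate.gamma(analysis_index)
    return prob_exceeds_by(post_E, post_S, gate.delta) < gamma


def evaluate_cohort(
    data: tuple[tuple[ArmCounts, ArmCounts], ...],
    rules: DecisionRuleSet,
    analysis_index: int,
    is_final: bool,
) -> Decision:
    """Combine both endpoints into a GO / STOP / CONTINUE verdict.

    ``data[k] = (treatment_counts, control_counts)`` for endpoint k. Efficacy
    is evaluated first; at an interim, futility is checked only when efficacy
    failed; at the final analysis STOP is the fallback.
    """
    if len(data) != rules.n_endpoints:
        raise ValueError(
            f"expected data for {rules.n_endpoints} endpoints, got {len(data)}"
        )
    posteriors = [
        (update(rules.prior, trt), update(rules.prior, ctl)) for trt, ctl in data
    ]

    efficacy_probs: list[tuple[float, ...]] = []
    endpoint_go: list[bool] = []
    required = rules.evidence_level_required
    for (post_e, post_s), levels in zip(posteriors, rules.levels):
        probs = []
        passed = True
        for lv in levels[:required]:
            p = prob_exceeds_by(post_e, post_s, lv.delta)
            probs.append(p)
            if p <= lv.gamma:
                passed = False
                break
        efficacy_probs.append(tuple(probs))
        endpoint_go.append(passed)

    go = any(endpoint_go) if rules.efficacy_combiner == "any" else all(endpoint_go)
    futility_probs: list[float | None] = [None] * rules.n_endpoints
    if go:
        verdict = GO
    elif is_final:
        verdict = STOP
    else:
        all_futile = True
        for k, ((post_e, post_s), gate) in enumerate(
            zip(posteriors, rules.futility)
        ):
            p = prob_exceeds_by(post_e, post_s, gate.delta)
            futility_probs[k] = p
            if not p < gate.gamma(analysis_index):
                all_futile = False
        verdict = STOP if all_futile else CONTINUE
    return Decision(
        verdict=verdict,
        efficacy_probs=tuple(efficacy_probs),
        futility_probs=tuple(futility_probs),
    )


def find_go_stop_overlap(
    rules: DecisionRuleSet,
    n_treatment: int,
    n_control: int,
    analysis_index: int,
) -> tuple[int, int] | None:
    """Scan one endpoint's count grid for data where GO and STOP both hold.

    GO and STOP can only overlap if some single endpoint is simultaneously
    efficacious and futile on the same data; this exhaustively checks all
    (treatment successes, control successes) pairs for each endpoint and
    returns the first offending pair, or None. Intended as a config-time
    sanity check at modest n.
    """
    for levels, gate in zip(rules.levels, rules.futility):
        for e in range(n_treatment + 1):
            for s in range(n_control + 1):
                post_e = update(rules.prior, ArmCounts(e, n_treatment))
                post_s = update(rules.prior, ArmCounts(s, n_control))
                if endpoint_futility(
                    post_e, post_s, gate, analysis_index
                ) and endpoint_efficacy(
                    post_e, post_s, levels, rules.evidence_level_required
                ):
                    return (e, s)
    return None
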