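"""Event-driven weekly simulation of the phase 2b platform trial.

The platform opens with two cohorts (treatment + matched control each); a new
cohort enters every 24 weeks up to a limit of five, on a fixed calendar that
does not react to early stops. Six participants accrue per week and are dealt
round-robin across cohorts open for enrollment; within a cohort, arms
alternate in randomized blocks of two (1:1 allocation, imbalance never above
one). Each participant's pair of binary outcomes is drawn from the
dichotomized-Gaussian joint law of their arm and becomes observable 52 weeks
after enrollment.

A cohort's analyses are triggered by its own count of observed outcomes
reaching 50% and 75% of the planned cohort size (interims) and the full size
(final). At an analysis the treatment counts come from the cohort's own
treatment arm; control counts come from its own control arm plus -- under
concurrent data sharing -- control participants of other cohorts enrolled
while this cohort was itself enrolling, with outcomes observed by the
analysis week. The decision rules may graduate (GO) or drop (STOP) the
cohort, which immediately closes its enrollment; the platform ends when every
cohort has a decision.

Within a week, events are ordered: outcome maturation, analyses (in cohort
entry order), enrollment. Accrual arriving when no cohort can enroll is lost
(never queued); with the default configuration that case never arises.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .bayes_posterior import ArmCounts
from .decision_rules import CONTINUE, DecisionRuleSet, GO, evaluate_cohort
from .joint_bernoulli import LatentCorrelationSpec, sample_joint, spec_from_latent_normal

__all__ = [
    "PlatformConfig",
    "Participant",
    "CohortState",
    "CohortRecord",
    "PlatformResult",
    "AllocationState",
    "cohort_schedule",
    "analysis_thresholds",
    "allocate_week",
    "draw_outcomes",
    "analysis_trigger",
    "analysis_data",
    "run_platform",
    "run_replicates",
    "replicate_rng",
]

SHARING_MODES = ("cohort", "concurrent")


@dataclass(frozen=True)
class PlatformConfig:
    """Every assumption and design choice of the platform, as one record.

    Defaults reproduce the base case: two initial cohorts, a new cohort every
    24 weeks up to five, 6 participants/week accrual, 52-week outcome lag,
    cohort size 150 (75 per arm), interims at 50%/75% of observed outcomes,
    concurrent control sharing, SoC responder rates 10%/20%, treatment rates
    equal to SoC (the null scenario), no time trend.
    """

    n_initial_cohorts: int = 2
    max_cohorts: int = 5
    cohort_entry_interval_weeks: int = 24
    accrual_per_week: int = 6
    outcome_lag_weeks: int = 52
    cohort_size: int = 150
    interim_fractions: tuple[float, ...] = (0.5, 0.75)
    sharing_mode: str = "concurrent"
    soc_rates: tuple[float, float] = (0.10, 0.20)
    trt_rates: tuple[float, float] = (0.10, 0.20)
    rho: float = 0.0
    time_trend_per_week: float = 0.0
    rules: DecisionRuleSet = field(default_factory=DecisionRuleSet.default)
    n_sims: int = 10_000
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("interim_fractions", "soc_rates", "trt_rates"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        for name in (
            "n_initial_cohorts",
            "max_cohorts",
            "accrual_per_week",
            "outcome_lag_weeks",
            "cohort_size",
            "n_sims",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.cohort_entry_interval_weeks < 0:
            raise ValueError("cohort_entry_interval_weeks must be non-negative")
        if self.n_initial_cohorts > self.max_cohorts:
            raise ValueError("n_initial_cohorts cannot exceed max_cohorts")
        if self.cohort_size % 2 != 0:
            raise ValueError(
                f"cohort_size={self.cohort_size!r} must be even for 1:1 blocks"
            )
        fractions = tuple(self.interim_fractions)
        if any(not 0.0 < f < 1.0 for f in fractions):
            raise ValueError(f"interim fractions {fractions!r} must lie in (0, 1)")
        if any(b <= a for a, b in zip(fractions, fractions[1:])):
            raise ValueError(f"interim fractions {fractions!r} must strictly increase")
        if self.sharing_mode not in SHARING_MODES:
            raise ValueError(
                f"sharing_mode={self.sharing_mode!r} not in {SHARING_MODES}"
            )
        for name in ("soc_rates", "trt_rates"):
            rates = getattr(self, name)
            if len(rates) != 2 or any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"{name}={rates!r} must be two probabilities")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho={self.rho!r} must lie in (-1, 1)")
        if len(fractions) != self.rules.n_interims:
            raise ValueError(
                f"{len(fractions)} interim fractions but futility gates for "
                f"{self.rules.n_interims} interims"
            )
        if self.time_trend_per_week != 0.0:
            horizon = self.enrollment_horizon_weeks
            drift = self.time_trend_per_week * horizon
            for name in ("soc_rates", "trt_rates"):
                for r in getattr(self, name):
                    if not 0.0 <= r + drift <= 1.0:
                        raise ValueError(
                            f"time trend pushes {name} rate {r} outside [0, 1] "
                            f"within the {horizon}-week enrollment horizon"
                        )

    @property
    def enrollment_horizon_weeks(self) -> int:
        """Latest week at which anyone could still be enrolled."""
        last_entry = self.cohort_entry_interval_weeks * (
            self.max_cohorts - self.n_initial_cohorts
        )
        return last_entry + math.ceil(
            self.max_cohorts * self.cohort_size / self.accrual_per_week
        )

    @property
    def n_analyses(self) -> int:
        return len(self.interim_fractions) + 1

    def with_overrides(self, **kwargs) -> "PlatformConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Participant:
    """A single randomized participant (used by the one-at-a-time API)."""

    enrollment_week: int
    cohort_id: int
    arm: str  # "treatment" or "control"
    outcome_lag_weeks: int = 52
    outcomes: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.outcome_lag_weeks <= 0:
            raise ValueError("outcome_lag_weeks must be positive")

    @property
    def outcome_week(self) -> int:
        return self.enrollment_week + self.outcome_lag_weeks


class CohortState:
    """Mutable per-cohort ledger of enrollment batches and observed counts.

    Enrollment is stored as weekly per-arm batches ``(week, n, s1, s2)`` with
    cumulative sums, so observed-by-week counts and enrollment-window sums are
    O(log n) prefix/range lookups. Status moves one way through
    enrolling -> awaiting_outcomes -> stopped_efficacy | stopped_futility.
    """

    __slots__ = (
        "cohort_id",
        "entry_week",
        "size",
        "lag",
        "enrolled_t",
        "enrolled_c",
        "block_next",
        "first_enroll_week",
        "last_enroll_week",
        "weeks_t",
        "cum_n_t",
        "cum_s1_t",
        "cum_s2_t",
        "weeks_c",
        "cum_n_c",
        "cum_s1_c",
        "cum_s2_c",
        "next_analysis",
        "decision",
        "decision_week",
        "decision_analysis",
    )

    def __init__(self, cohort_id: int, entry_week: int, size: int, lag: int):
        self.cohort_id = cohort_id
        self.entry_week = entry_week
        self.size = size
        self.lag = lag
        self.enrolled_t = 0
        self.enrolled_c = 0
        self.block_next: str | None = None
        self.first_enroll_week: int | None = None
        self.last_enroll_week: int | None = None
        # per-arm batch ledgers: enrollment week + cumulative n / successes
        self.weeks_t: list[int] = []
        self.cum_n_t: list[int] = [0]
        self.cum_s1_t: list[int] = [0]
        self.cum_s2_t: list[int] = [0]
        self.weeks_c: list[int] = []
        self.cum_n_c: list[int] = [0]
        self.cum_s1_c: list[int] = [0]
        self.cum_s2_c: list[int] = [0]
        self.next_analysis = 0  # index into analysis_thresholds(config)
        self.decision: str | None = None
        self.decision_week: int | None = None
        self.decision_analysis: int | None = None

    # -- status -------------------------------------------------------------

    @property
    def active(self) -> bool:
        return self.decision is None

    @property
    def total_enrolled(self) -> int:
        return self.enrolled_t + self.enrolled_c

    @property
    def is_full(self) -> bool:
        return self.total_enrolled >= self.size

    def open_for_enrollment(self, week: int) -> bool:
        return self.active and not self.is_full and week >= self.entry_week

    @property
    def status(self) -> str:
        if self.decision == GO:
            return "stopped_efficacy"
        if self.decision == "STOP":
            return "stopped_futility"
        return "awaiting_outcomes" if self.is_full else "enrolling"

    # -- enrollment ---------------------------------------------------------

    def record_batch(
        self, week: int, arm: str, n: int, s1: int, s2: int
    ) -> None:
        if n <= 0:
            return
        if arm == "treatment":
            weeks, cn, c1, c2 = self.weeks_t, self.cum_n_t, self.cum_s1_t, self.cum_s2_t
            self.enrolled_t += n
        else:
            weeks, cn, c1, c2 = self.weeks_c, self.cum_n_c, self.cum_s1_c, self.cum_s2_c
            self.enrolled_c += n
        weeks.append(week)
        cn.append(cn[-1] + n)
        c1.append(c1[-1] + s1)
        c2.append(c2[-1] + s2)
        if self.first_enroll_week is None:
            self.first_enroll_week = week
        self.last_enroll_week = week

    # -- observed-count lookups ---------------------------------------------

    def _prefix(self, weeks, cum, through_week: int) -> int:
        return cum[bisect_right(weeks, through_week)]

    def observed_total(self, week: int) -> int:
        """Cohort participants (both arms) with outcomes observed by *week*."""
        cutoff = week - self.lag
        return self._prefix(self.weeks_t, self.cum_n_t, cutoff) + self._prefix(
            self.weeks_c, self.cum_n_c, cutoff
        )

    def observed_arm(self, arm: str, week: int) -> tuple[int, int, int]:
        """(n, endpoint-1 successes, endpoint-2 successes) observed by week."""
        cutoff = week - self.lag
        if arm == "treatment":
            weeks, cn, c1, c2 = self.weeks_t, self.cum_n_t, self.cum_s1_t, self.cum_s2_t
        else:
            weeks, cn, c1, c2 = self.weeks_c, self.cum_n_c, self.cum_s1_c, self.cum_s2_c
        i = bisect_right(weeks, cutoff)
        return cn[i], c1[i], c2[i]

    def control_window_sum(
        self, week_lo: int, week_hi: int, observed_by: int
    ) -> tuple[int, int, int]:
        """Control participants enrolled in [week_lo, week_hi], observed by
        *observed_by*: returns (n, s1, s2)."""
        hi = min(week_hi, observed_by - self.lag)
        if hi < week_lo:
            return 0, 0, 0
        j = bisect_right(self.weeks_c, hi)
        i = bisect_right(self.weeks_c, week_lo - 1)
        return (
            self.cum_n_c[j] - self.cum_n_c[i],
            self.cum_s1_c[j] - self.cum_s1_c[i],
            self.cum_s2_c[j] - self.cum_s2_c[i],
        )

    def decide(self, verdict: str, week: int, analysis_index: int) -> None:
        if not self.active:
            raise RuntimeError("cohort already has a decision")
        self.decision = verdict
        self.decision_week = week
        self.decision_analysis = analysis_index


@dataclass(frozen=True)
class CohortRecord:
    """Immutable summary of one cohort's fate within a replicate."""

    cohort_id: int
    entry_week: int
    decision: str  # GO or STOP
    analysis_index: int
    decision_week: int
    enrolled_treatment: int
    enrolled_control: int


@dataclass(frozen=True)
class PlatformResult:
    """Per-replicate outcome: one record per cohort plus platform totals."""

    cohorts: tuple[CohortRecord, ...]
    platform_duration_weeks: int
    total_enrolled: int


# ---------------------------------------------------------------------------
# schedule / allocation


def cohort_schedule(config: PlatformConfig) -> list[int]:
    """Fixed calendar of cohort entry weeks, independent of early stops."""
    entries = [0] * config.n_initial_cohorts
    week = 0
    while len(entries) < config.max_cohorts:
        week += config.cohort_entry_interval_weeks
        entries.append(week)
    return entries


def analysis_thresholds(config: PlatformConfig) -> list[int]:
    """Observed-outcome counts that trigger each analysis (final = size)."""
    interims = [math.ceil(f * config.cohort_size) for f in config.interim_fractions]
    return interims + [config.cohort_size]


@dataclass
class AllocationState:
    """Persistent round-robin cursor so long-run allocation is exactly equal."""

    cursor: int = 0


def allocate_week(
    week: int,
    open_cohorts: list[CohortState],
    accrual: int,
    carry_state: AllocationState,
) -> dict[int, int]:
    """Deal the week's accrual across cohorts open for enrollment.

    Participants are dealt one at a time round-robin from a persistent cursor,
    which splits each week as evenly as possible and rotates any remainder so
    long-run counts stay equal. Cohorts at capacity are skipped; accrual left
    over when every cohort is full is lost.
    """
    if accrual < 0:
        raise ValueError("accrual must be non-negative")
    eligible = sorted(
        (c for c in open_cohorts if c.open_for_enrollment(week)),
        key=lambda c: c.cohort_id,
    )
    assigned: dict[int, int] = {c.cohort_id: 0 for c in eligible}
    capacity = {c.cohort_id: c.size - c.total_enrolled for c in eligible}
    for _ in range(accrual):
        todo = [c for c in eligible if capacity[c.cohort_id] - assigned[c.cohort_id] > 0]
        if not todo:
            break  # all open cohorts full; remaining accrual is lost
        pick = todo[carry_state.cursor % len(todo)]
        assigned[pick.cohort_id] += 1
        carry_state.cursor += 1
    return {cid: n for cid, n in assigned.items() if n > 0}


def _assign_arms(
    cohort: CohortState, n: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Split n new participants into (treatment, control) by blocks of two."""
    half = cohort.size // 2
    n_t = n_c = 0
    for _ in range(n):
        if cohort.enrolled_t + n_t >= half:
            arm = "control"
            cohort.block_next = None
        elif cohort.enrolled_c + n_c >= half:
            arm = "treatment"
            cohort.block_next = None
        elif cohort.block_next is not None:
            arm = cohort.block_next
            cohort.block_next = None
        else:
            arm = "treatment" if rng.integers(2) == 0 else "control"
            cohort.block_next = "control" if arm == "treatment" else "treatment"
        if arm == "treatment":
            n_t += 1
        else:
            n_c += 1
    return n_t, n_c


# ---------------------------------------------------------------------------
# outcome generation


@lru_cache(maxsize=1024)
def _cell_probs(rate1: float, rate2: float, rho: float) -> tuple[float, ...]:
    if rho == 0.0:
        q1, q2 = 1.0 - rate1, 1.0 - rate2
        return (q1 * q2, q1 * rate2, rate1 * q2, rate1 * rate2)
    spec = spec_from_latent_normal(
        LatentCorrelationSpec(p1_dot=rate1, p_dot1=rate2, rho=rho)
    )
    return (spec.p00, spec.p01, spec.p10, spec.p11)


def _arm_rates(config: PlatformConfig, arm: str, week: int) -> tuple[float, float]:
    base = config.trt_rates if arm == "treatment" else config.soc_rates
    drift = config.time_trend_per_week * week
    return (base[0] + drift, base[1] + drift)


def draw_outcomes(
    participant: Participant, config: PlatformConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw one participant's (endpoint-1, endpoint-2) outcome pair."""
    r1, r2 = _arm_rates(config, participant.arm, participant.enrollment_week)
    if 0.0 < r1 < 1.0 and 0.0 < r2 < 1.0 and config.rho != 0.0:
        spec = spec_from_latent_normal(
            LatentCorrelationSpec(p1_dot=r1, p_dot1=r2, rho=config.rho)
        )
        s, l = sample_joint(spec, 1, rng)[0]
    else:
        # degenerate or independent marginals
        s = int(rng.random() < r1)
        l = int(rng.random() < r2)
    return int(s), int(l)


def _draw_batch(
    config: PlatformConfig, arm: str, week: int, n: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Endpoint-1 and endpoint-2 success counts among n new participants."""
    r1, r2 = _arm_rates(config, arm, week)
    if not (0.0 < r1 < 1.0 and 0.0 < r2 < 1.0):
        s1 = int(rng.binomial(n, min(1.0, max(0.0, r1))))
        s2 = int(rng.binomial(n, min(1.0, max(0.0, r2))))
        return s1, s2
    cells = rng.multinomial(n, _cell_probs(r1, r2, config.rho))
    return int(cells[2] + cells[3]), int(cells[1] + cells[3])


# ---------------------------------------------------------------------------
# analyses


def analysis_trigger(
    cohort: CohortState, week: int, config: PlatformConfig
) -> int | None:
    """Analysis index (1-based) due for this cohort this week, else None."""
    if not cohort.active:
        return None
    thresholds = analysis_thresholds(config)
    if cohort.next_analysis >= len(thresholds):
        return None
    if cohort.observed_total(week) >= thresholds[cohort.next_analysis]:
        return cohort.next_analysis + 1
    return None


def analysis_data(
    cohort: CohortState,
    all_cohorts: list[CohortState],
    week: int,
    mode: str,
) -> tuple[tuple[ArmCounts, ArmCounts], ...]:
    """Per-endpoint (treatment, control) counts entering a decision.

    Treatment counts are always the cohort's own observed treatment arm.
    Control counts are the cohort's own observed controls plus, in concurrent
    mode, observed controls of other cohorts enrolled inside this cohort's
    enrollment window (up to the current week while it is still enrolling).
    """
    if mode not in SHARING_MODES:
        raise ValueError(f"unknown sharing mode {mode!r}")
    n_t, s1_t, s2_t = cohort.observed_arm("treatment", week)
    n_c, s1_c, s2_c = cohort.observed_arm("control", week)
    if mode == "concurrent" and cohort.first_enroll_week is not None:
        window_lo = cohort.first_enroll_week
        still_enrolling = cohort.active and not cohort.is_full
        window_hi = week if still_enrolling else cohort.last_enroll_week
        for other in all_cohorts:
            if other is cohort:
                continue
            n, s1, s2 = other.control_window_sum(window_lo, window_hi, week)
            n_c += n
            s1_c += s1
            s2_c += s2
    return (
        (ArmCounts(s1_t, n_t), ArmCounts(s1_c, n_c)),
        (ArmCounts(s2_t, n_t), ArmCounts(s2_c, n_c)),
    )


# ---------------------------------------------------------------------------
# platform loop


def run_platform(
    config: PlatformConfig,
    rng: np.random.Generator,
    trace: list | None = None,
) -> PlatformResult:
    """Simulate one platform trajectory to completion.

    Weekly event order: outcome maturation (implicit in observed-by-week
    lookups), analyses in cohort entry order, enrollment. Termination is
    guaranteed because the final analysis always returns GO or STOP.
    """
    cohorts = [
        CohortState(i, entry, config.cohort_size, config.outcome_lag_weeks)
        for i, entry in enumerate(cohort_schedule(config))
    ]
    alloc_state = AllocationState()
    n_final = config.n_analyses
    thresholds = analysis_thresholds(config)
    week = 0
    max_weeks = config.enrollment_horizon_weeks + config.outcome_lag_weeks + 104
    while any(c.active for c in cohorts):
        if week > max_weeks:
            raise RuntimeError("platform failed to terminate; check configuration")
        # analyses, in cohort entry order; several can fire in one week
        for cohort in cohorts:
            while cohort.active and cohort.next_analysis < len(thresholds):
                if cohort.observed_total(week) < thresholds[cohort.next_analysis]:
                    break
                idx = cohort.next_analysis + 1
                data = analysis_data(cohort, cohorts, week, config.sharing_mode)
                decision = evaluate_cohort(
                    data, config.rules, idx, is_final=(idx == n_final)
                )
                cohort.next_analysis += 1
                if trace is not None:
                    trace.append(
                        (week, "analysis", cohort.cohort_id, idx, decision.verdict)
                    )
                if decision.verdict != CONTINUE:
                    cohort.decide(decision.verdict, week, idx)
        # enrollment
        assignments = allocate_week(week, cohorts, config.accrual_per_week, alloc_state)
        for cid, n in assignments.items():
            cohort = cohorts[cid]
            n_t, n_c = _assign_arms(cohort, n, rng)
            if n_t:
                s1, s2 = _draw_batch(config, "treatment", week, n_t, rng)
                cohort.record_batch(week, "treatment", n_t, s1, s2)
            if n_c:
                s1, s2 = _draw_batch(config, "control", week, n_c, rng)
                cohort.record_batch(week, "control", n_c, s1, s2)
            if trace is not None:
                trace.append((week, "enroll", cid, n_t, n_c))
        week += 1

    records = tuple(
        CohortRecord(
            cohort_id=c.cohort_id,
            entry_week=c.entry_week,
            decision=c.decision,
            analysis_index=c.decision_analysis,
            decision_week=c.decision_week,
            enrolled_treatment=c.enrolled_t,
            enrolled_control=c.enrolled_c,
        )
        for c in cohorts
    )
    return PlatformResult(
        cohorts=records,
        platform_duration_weeks=max(c.decision_week for c in cohorts),
        total_enrolled=sum(c.total_enrolled for c in cohorts),
    )


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, order-free random stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence([seed, replicate]))


def run_replicates(
    config: PlatformConfig,
    n_sims: int | None = None,
    seed: int | None = None,
) -> list[PlatformResult]:
    """Run independent platform replicates with per-replicate streams."""
    n = config.n_sims if n_sims is None else n_sims
    base = config.seed if seed is None else seed
    return [run_platform(config, replicate_rng(base, rep)) for rep in range(n)]
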