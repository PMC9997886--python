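# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `nashplat`, in the spirit of a model-description
appendix.

## Correlated binary endpoints

For a participant on arm *k* the outcome pair (S, L) — endpoint 1 (NASH
resolution) and endpoint 2 (fibrosis improvement) — follows a bivariate
Bernoulli law with cells p00, p01, p10, p11 (`pij = P(S=i, L=j)`) and
Pearson correlation

    phi = (p11 − p1·p·1) / sqrt(p0· p1· p·0 p·1).

Four constructions are implemented (`joint_bernoulli`):

1. **Direct**: fix three cells, the fourth is the remainder.
2. **Sens/spec**: fix P(S=1) plus sensitivity/specificity of S for L;
   always feasible for inputs in [0, 1].
3. **Phi**: fix both marginals and φ; φ is bounded by the marginals
   (`phi_bounds`), and out-of-range requests raise with the attainable
   interval. The bounds are exactly those obtained by enumerating all valid
   2×2 tables with the given marginals (tested against that brute force).
4. **Latent Gaussian** (the simulator's default): fix both marginals and a
   latent bivariate-normal correlation ρ; cells are Gaussian quadrant
   masses.

For construction 4 the thresholds are the standard-normal quantiles of the
*failure* probabilities, i.e. p00 = Φ₂(Φ⁻¹(p0·), Φ⁻¹(p·0); ρ). This is the
unique thresholding that preserves the requested marginals, which is the
whole point of specifying them; the remaining cells are filled by
inclusion–exclusion from the marginals so marginal preservation is exact by
construction. Φ₂ is evaluated through Owen's T function
(`scipy.special.owens_t`), which is deterministic and accurate to roughly
machine precision (validated in the test suite against an independent
numerical integral and a Monte-Carlo oracle); the package-wide tolerance
claimed for quadrant masses is 1e-9.

The achieved binary correlation `rho_to_phi(p1, p2, ρ)` is monotone in ρ,
maps 0 to 0, and is compressed toward 0 as the marginals move away from
0.5/0.5 — users specifying "the correlation" as ρ should be aware that φ
can be much smaller. A related caveat: a published illustration of this
design reports 69 (ρ = −0.3) and 53 (ρ = 0.7) expected
at-least-one-endpoint responders per 100 for rates 30%/40%, while the
quadrant-probability computation here gives ≈62 and ≈47; those illustration
head-counts are not used as checks anywhere in this package.

Sampling uses one four-cell multinomial draw per participant (batched per
week and arm in the engine) rather than latent-normal draws; the two are
distributionally identical and the multinomial is far cheaper. Cell values
within 1e-12 of 0 or 1 are snapped to the boundary; larger violations
raise.

## Posterior decision probabilities

Each (arm, endpoint) response rate carries a Beta(1, 1) prior — the design's
"weakly informative" choice — updated conjugately on observed counts. All
gates threshold

    P(pi_E > pi_S + delta | D)
      = ∫ f_S(u) · (1 − F_E(min(1, u + delta))) du,

computed by fixed-order (160-point) Gauss–Legendre quadrature over the
interval of [0, 1−δ] that carries control-posterior mass beyond 1e-14 per
tail. For the integer-count posteriors the engine produces, the absolute
error is far below the 1e-6 target (verified against 10⁶-draw Monte-Carlo
oracles and the complement identity P(E>S) + P(S>E) = 1). Shape parameters
below 1 put a power-law singularity at an endpoint; those cases are routed
to adaptive quadrature instead. Results are memoized on
(α_E, β_E, α_S, β_S, δ): a decision is a pure function of observed counts,
so caching is sound and is what makes 10,000-replicate sweeps fast.
"Confidence above γ" is implemented as a strict inequality (> γ), matching
the design's formal statement; at floating-point resolution the distinction
is untestable, and γ = 1 usefully disables a gate under strict comparison.

## Decision rules

Efficacy levels per endpoint (δ, γ): endpoint 1 (0, 0.95), (0.30, 0.85),
(0.40, 0.60); endpoint 2 (0, 0.95), (0.175, 0.85), (0.25, 0.60); identical
at every analysis. Margins must strictly increase and confidences strictly
decrease across levels. The required evidence level (default 3) is
conjunctive and hierarchical, so success probability is non-increasing in
the level. Futility margins are 0.25 (endpoint 1) and 0.10 (endpoint 2)
with thresholds 0.20 at interim 1 and 0.30 at interim 2; there is no
futility gate at the final analysis — failing efficacy there is futility.
(The design's formal parameter listing contains one index slip for the
final-analysis threshold; it is read as the futility gate's absence, which
matches the verbal description.)

Combination across endpoints: GO if *either* endpoint is efficacious (FDA
"OR"; an "AND" combiner is available in the configuration but not exercised
by default), STOP at interim only if *both* endpoints are futile. When the
raw GO and STOP conditions would both hold, efficacy wins; the
parameterization is expected to preclude this, and `find_go_stop_overlap`
can exhaustively scan a count grid to verify it for a given sample size
(the default rules admit no overlap at the sizes checked).

## Trial engine

Time advances in whole weeks; within a week the order is (1) outcome
maturation, (2) analyses in cohort entry order, (3) enrollment. This makes
an analysis "counting observed outcomes" see the week's matured outcomes,
and prevents enrolling into a cohort stopped the same week.

* **Accrual** is deterministic at 6/week (the design documents an
  approximate rate, not a distribution); participants are dealt one at a
  time round-robin across open cohorts from a persistent cursor, so weekly
  splits are as even as possible and long-run allocation is exactly equal.
  Accrual with no open cohort is lost, not queued; with the default
  parameters the case never arises.
* **Cohort entry** is a fixed calendar ([0, 0, 24, 48, 72] by default)
  independent of earlier stops, matching a platform that always evaluates
  five treatments.
* **Randomization** within a cohort alternates arms in blocks of two with
  random block order; per-arm imbalance never exceeds one.
* **Analyses** trigger when the cohort's own observed-outcome count (both
  arms) first reaches ⌈0.5·N⌉, ⌈0.75·N⌉ and N (ceiling on fractional
  counts, e.g. 113 of 150); a stopped cohort's remaining analyses are
  skipped, never back-filled.
* **Concurrent control sharing** pools other cohorts' control participants
  whose enrollment week lies within the index cohort's enrollment window
  (first enrollment through last, treated as still open while the cohort is
  enrolling) and whose outcomes are observed by the analysis week.
  Cohort-only mode shares nothing. The concurrent pool is by construction a
  superset of the cohort-only pool.
* **Time trend** (additive weekly drift on all response probabilities) is
  supported and validated against leaving [0, 1] over the enrollment
  horizon; the default is 0, as in the base design.

Each replicate uses an independent stream derived from (seed, replicate
index), so replicates are order-independent and a replicate ledger can be
reproduced bit-exactly from its manifest.

## Operating characteristics

All cohorts in a replicate share one treatment-effect scenario and are
exchangeable, so the success probability pools cohort decisions across
replicates (5 × n_sims evaluations) and its binomial standard error uses
the pooled count. Duration (week of the last cohort decision) and total
enrollment are averaged per replicate; "participants saved" is the planned
total (max_cohorts × cohort_size) minus mean enrollment. Scenario grids are
Cartesian products with counter-derived per-scenario seeds; monotonicity
patterns (success non-increasing in evidence level and in ρ, non-decreasing
in effect size) are tested with common random numbers across scenarios.

## Problem sizes and synthetic-data realism

The default replicate count is 10,000 per scenario, which is what
`scripts/acceptance.py` uses; the test suite scales stochastic checks down
to 1,000–2,000 replicates (pooling 5,000–10,000 cohort evaluations) and
widens its tolerances to max(4 Monte-Carlo standard errors, the
"approximately" slack of the quoted value) accordingly. Two headline
scenarios deserve a note:

* **Futility elimination under the null** (treatment rates equal to SoC) is
  computed with cohort-only controls, reading "what the futility rules
  eliminate" as a property of a cohort's own data. With concurrent pooling
  the same quantities are a few points higher (≈65%/86% versus ≈61%/82% at
  the two interims) because the larger control pool sharpens the posterior.
* **The type-I-error scenario** (treatment 10%/25% against SoC 10%/20%)
  comes out near 0.4% here rather than the ~0.1% sometimes quoted for this
  family of designs. The mechanism is structural: endpoint 2 carries a true
  5-point benefit, and because the same margins and confidences apply at
  every analysis, the interim looks — taken when only about half the
  participants have observed outcomes, so the posterior is wide — are the
  dominant source of spurious graduations; a design with a final analysis
  only would sit well below 0.1%. Readers comparing against figures where
  this value is read off a plot near zero should expect that resolution
  difference.
* **Participant savings** under overwhelming efficacy are reported against
  a planned total of 1,500, the figure used in the design's own summary,
  although five cohorts of 250 plan 1,250 enrollments; the reported saving
  therefore mixes a 250-participant structural margin with the
  early-stopping effect. The engine's enrollment ledger makes either
  accounting available.

The generator emulates the design's stated world: fixed accrual, exact
52-week lag, homogeneous participants, no dropout or missing biopsies, no
platform-level multiplicity adjustment, identical true effects for all
cohorts. Passing tests therefore demonstrate the design's operating
characteristics under those idealizations, not robustness to staggered
accrual, outcome drift (unless configured), population heterogeneity or
missingness in real trials.

## Known limitations

Two endpoints only; Gaussian copula only (no other dependence structures);
conjugate Beta models only (no shrinkage across cohorts, no non-concurrent
borrowing); fixed 1:1 randomization (no response-adaptive allocation);
frequentist group-sequential comparators are out of scope.
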