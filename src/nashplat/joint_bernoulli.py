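"""Bivariate Bernoulli distributions for two correlated binary endpoints.

A trial participant contributes a pair of binary outcomes: a short-term
endpoint ``S`` (here, NASH resolution without worsening of fibrosis) and a
long-term endpoint ``L`` (>=1-stage fibrosis improvement without worsening of
NASH). Their joint law is a four-cell table ``(p00, p01, p10, p11)`` with
``pij = P(S=i, L=j)``. This module offers the four standard constructions of
such a table --

* direct specification of three cells,
* one marginal plus sensitivity/specificity of ``S`` for ``L``,
* both marginals plus the Pearson phi correlation (bounded by the marginals),
* both marginals plus a latent bivariate-normal correlation ``rho``
  (dichotomized Gaussian / tetrachoric construction),

-- together with the inverse summaries (``phi_of``, ``diagnostics_of``,
``rho_to_phi``), the attainable phi interval ``phi_bounds``, and i.i.d.
sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri, owens_t

__all__ = [
    "JointBernoulliSpec",
    "DiagnosticProfile",
    "LatentCorrelationSpec",
    "spec_from_direct",
    "spec_from_sens_spec",
    "spec_from_phi",
    "spec_from_latent_normal",
    "phi_bounds",
    "phi_of",
    "diagnostics_of",
    "rho_to_phi",
    "bivariate_normal_cdf",
    "sample_joint",
]

#: absolute slack within which cell probabilities are snapped to [0, 1]
_BOUNDARY_TOL = 1e-12


def _snap_unit(value: float, name: str) -> float:
    """Clip *value* to [0, 1] if within 1e-12 of the boundary, else validate."""
    if -_BOUNDARY_TOL <= value < 0.0:
        return 0.0
    if 1.0 < value <= 1.0 + _BOUNDARY_TOL:
        return 1.0
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value!r} lies outside [0, 1]")
    return float(value)


@dataclass(frozen=True)
class JointBernoulliSpec:
    """Joint probability table of the bivariate Bernoulli outcome (S, L).

    ``pij = P(S=i, L=j)``; the cells must be non-negative and sum to one
    (within 1e-12). Marginals are exposed as ``p1_dot = P(S=1)`` and
    ``p_dot1 = P(L=1)``.
    """

    p00: float
    p01: float
    p10: float
    p11: float

    def __post_init__(self) -> None:
        for name in ("p00", "p01", "p10", "p11"):
            object.__setattr__(self, name, _snap_unit(getattr(self, name), name))
        total = self.p00 + self.p01 + self.p10 + self.p11
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities sum to {total!r}, not 1")

    @property
    def p1_dot(self) -> float:
        """Marginal success probability of the short-term endpoint S."""
        return self.p10 + self.p11

    @property
    def p_dot1(self) -> float:
        """Marginal success probability of the long-term endpoint L."""
        return self.p01 + self.p11

    @property
    def p0_dot(self) -> float:
        return self.p00 + self.p01

    @property
    def p_dot0(self) -> float:
        return self.p00 + self.p10

    def cell_probs(self) -> np.ndarray:
        """Cells in the fixed order (p00, p01, p10, p11)."""
        return np.array([self.p00, self.p01, self.p10, self.p11])


@dataclass(frozen=True)
class DiagnosticProfile:
    """Conditional (diagnostic) summaries of a joint table plus its phi.

    ``sens_SL = P(S=1 | L=1)``-style quantities follow the surrogate-endpoint
    reading: sensitivity/specificity of the short-term endpoint in predicting
    the long-term one and vice versa.
    """

    sens_SL: float
    spec_SL: float
    sens_LS: float
    spec_LS: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("sens_SL", "spec_SL", "sens_LS", "spec_LS"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0 + _BOUNDARY_TOL:
                raise ValueError(f"{name}={value!r} outside [0, 1]")
        if not -1.0 - _BOUNDARY_TOL <= self.phi <= 1.0 + _BOUNDARY_TOL:
            raise ValueError(f"phi={self.phi!r} outside [-1, 1]")


@dataclass(frozen=True)
class LatentCorrelationSpec:
    """Marginals plus latent Gaussian correlation, the simulator's native input.

    ``rho`` is the correlation of the latent bivariate-normal pair prior to
    dichotomization, not the phi correlation of the binary outcomes.
    """

    p1_dot: float
    p_dot1: float
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p1_dot < 1.0:
            raise ValueError(f"p1_dot={self.p1_dot!r} must lie in (0, 1)")
        if not 0.0 < self.p_dot1 < 1.0:
            raise ValueError(f"p_dot1={self.p_dot1!r} must lie in (0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho={self.rho!r} must lie in (-1, 1)")


# ---------------------------------------------------------------------------
# constructions


def spec_from_direct(p00: float, p10: float, p01: float) -> JointBernoulliSpec:
    """Direct specification: fix three cells, ``p11`` is the remainder."""
    for name, value in (("p00", p00), ("p10", p10), ("p01", p01)):
        if value < -_BOUNDARY_TOL:
            raise ValueError(f"{name}={value!r} is negative")
    total = p00 + p10 + p01
    if total > 1.0 + _BOUNDARY_TOL:
        raise ValueError(f"p00 + p10 + p01 = {total!r} exceeds 1")
    return JointBernoulliSpec(p00=p00, p01=p01, p10=p10, p11=1.0 - total)


def spec_from_sens_spec(
    p1_dot: float, sens_SL: float, spec_SL: float
) -> JointBernoulliSpec:
    """Implicit specification via one marginal and sens/spec of S for L.

    Always yields a valid table for inputs in [0, 1]:
    ``p11 = sens_SL * p1_dot`` and ``p00 = spec_SL * (1 - p1_dot)``.
    """
    for name, value in (
        ("p1_dot", p1_dot),
        ("sens_SL", sens_SL),
        ("spec_SL", spec_SL),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name}={value!r} outside [0, 1]")
    p11 = sens_SL * p1_dot
    p00 = spec_SL * (1.0 - p1_dot)
    p10 = p1_dot - p11
    p01 = (1.0 - p1_dot) - p00
    return JointBernoulliSpec(p00=p00, p01=p01, p10=p10, p11=p11)


def phi_bounds(p1_dot: float, p_dot1: float) -> tuple[float, float]:
    """Attainable interval of the phi correlation given both marginals.

    For fixed marginals the binary correlation cannot be chosen freely; the
    bounds follow from requiring all four cells to be non-negative.
    """
    for name, value in (("p1_dot", p1_dot), ("p_dot1", p_dot1)):
        if not 0.0 < value < 1.0:
            raise ValueError(
                f"{name}={value!r} must lie strictly in (0, 1); "
                "the phi bounds degenerate at 0 or 1"
            )
    a, b = p1_dot, p_dot1
    qa, qb = 1.0 - a, 1.0 - b
    lower = max(-math.sqrt((a * b) / (qa * qb)), -math.sqrt((qa * qb) / (a * b)))
    upper = min(math.sqrt((a * qb) / (qa * b)), math.sqrt((qa * b) / (a * qb)))
    return max(lower, -1.0), min(upper, 1.0)


def spec_from_phi(p1_dot: float, p_dot1: float, phi: float) -> JointBernoulliSpec:
    """Implicit specification via both marginals and the phi correlation.

    ``p11 = phi * sqrt(p0. * p1. * p.0 * p.1) + p1. * p.1``; the remaining
    cells follow from the marginals. Raises if *phi* lies outside the
    attainable interval for these marginals.
    """
    lower, upper = phi_bounds(p1_dot, p_dot1)
    if not lower - _BOUNDARY_TOL <= phi <= upper + _BOUNDARY_TOL:
        raise ValueError(
            f"phi={phi!r} is not attainable for marginals "
            f"({p1_dot}, {p_dot1}); the attainable interval is "
            f"[{lower:.6f}, {upper:.6f}]"
        )
    q1, q2 = 1.0 - p1_dot, 1.0 - p_dot1
    p11 = phi * math.sqrt(q1 * p1_dot * q2 * p_dot1) + p1_dot * p_dot1
    p01 = p_dot1 - p11
    p10 = p1_dot - p11
    p00 = 1.0 - (p11 + p01 + p10)
    return JointBernoulliSpec(p00=p00, p01=p01, p10=p10, p11=p11)


def _owens_t(h: float, a: float) -> float:
    """Owen's T function, extended to infinite second argument."""
    if math.isinf(a):
        t = 0.5 * float(ndtr(-abs(h)))
        return t if a > 0 else -t
    return float(owens_t(h, a))


def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Computed from Owen's T function, which is exact to machine precision and
    deterministic (no adaptive cubature is involved).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho={rho!r} must lie in (-1, 1)")
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    denom = math.sqrt(1.0 - rho * rho)
    if h != 0.0:
        a_h = (k - rho * h) / (h * denom)
    else:
        a_h = math.inf if (k - rho * h) > 0 else -math.inf
    if k != 0.0:
        a_k = (h - rho * k) / (k * denom)
    else:
        a_k = math.inf if (h - rho * k) > 0 else -math.inf
    hk = h * k
    if hk > 0.0 or (hk == 0.0 and h + k >= 0.0):
        beta = 0.0
    else:
        beta = 0.5
    value = (
        0.5 * (float(ndtr(h)) + float(ndtr(k)))
        - _owens_t(h, a_h)
        - _owens_t(k, a_k)
        - beta
    )
    return min(1.0, max(0.0, value))


def spec_from_latent_normal(spec: LatentCorrelationSpec) -> JointBernoulliSpec:
    """Dichotomized-Gaussian construction from (p1_dot, p_dot1, rho).

    A latent standard bivariate normal pair with correlation ``rho`` is
    thresholded at the standard-normal quantiles of the failure probabilities,
    so the requested marginals are preserved exactly. ``p00`` is the lower
    quadrant mass; the other cells follow by inclusion-exclusion from the
    marginals (which guarantees exact marginal preservation).
    """
    z_s = float(ndtri(1.0 - spec.p1_dot))  # failure threshold for S
    z_l = float(ndtri(1.0 - spec.p_dot1))  # failure threshold for L
    p00 = bivariate_normal_cdf(z_s, z_l, spec.rho)
    p01 = (1.0 - spec.p1_dot) - p00
    p10 = (1.0 - spec.p_dot1) - p00
    p11 = 1.0 - (p00 + p01 + p10)
    return JointBernoulliSpec(p00=p00, p01=p01, p10=p10, p11=p11)


# ---------------------------------------------------------------------------
# summaries


def phi_of(spec: JointBernoulliSpec) -> float:
    """Pearson phi correlation of the two binary endpoints.

    ``phi = (p11 - p1. * p.1) / sqrt(p0. * p1. * p.0 * p.1)``; undefined when
    any marginal is degenerate.
    """
    denom_sq = spec.p0_dot * spec.p1_dot * spec.p_dot0 * spec.p_dot1
    if denom_sq <= 0.0:
        raise ValueError(
            "phi is undefined for degenerate marginals "
            f"(p1.={spec.p1_dot!r}, p.1={spec.p_dot1!r})"
        )
    phi = (spec.p11 - spec.p1_dot * spec.p_dot1) / math.sqrt(denom_sq)
    return min(1.0, max(-1.0, phi))


def diagnostics_of(spec: JointBernoulliSpec) -> DiagnosticProfile:
    """Sensitivity/specificity of each endpoint for the other, plus phi."""
    components = {
        "sens_SL": spec.p1_dot,
        "spec_SL": spec.p0_dot,
        "sens_LS": spec.p_dot1,
        "spec_LS": spec.p_dot0,
    }
    for name, marginal in components.items():
        if marginal <= 0.0:
            raise ValueError(f"{name} is undefined: its denominator marginal is 0")
    return DiagnosticProfile(
        sens_SL=min(1.0, spec.p11 / spec.p1_dot),
        spec_SL=min(1.0, spec.p00 / spec.p0_dot),
        sens_LS=min(1.0, spec.p11 / spec.p_dot1),
        spec_LS=min(1.0, spec.p00 / spec.p_dot0),
        phi=phi_of(spec),
    )


def rho_to_phi(p1_dot: float, p_dot1: float, rho: float) -> float:
    """Phi correlation achieved by the latent-normal construction.

    The mapping is non-linear, monotone in ``rho``, maps 0 to 0, and its range
    lies inside ``phi_bounds(p1_dot, p_dot1)``; the full interval [-1, 1] is
    achievable only for symmetric 0.5/0.5 marginals.
    """
    if rho == 0.0:
        return 0.0
    spec = spec_from_latent_normal(
        LatentCorrelationSpec(p1_dot=p1_dot, p_dot1=p_dot1, rho=rho)
    )
    return phi_of(spec)


# ---------------------------------------------------------------------------
# sampling


def sample_joint(
    spec: JointBernoulliSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. outcome pairs; returns an (n, 2) array of (s, l).

    Each pair is a single draw from the four-cell multinomial; this is
    distributionally equivalent to thresholding latent-normal draws but much
    cheaper.
    """
    if n < 0:
        raise ValueError(f"n={n!r} must be non-negative")
    if n == 0:
        return np.empty((0, 2), dtype=np.int8)
    cum = np.cumsum(spec.cell_probs())
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(n), side="right")
    out = np.empty((n, 2), dtype=np.int8)
    out[:, 0] = idx >= 2  # S success for cells p10, p11
    out[:, 1] = idx % 2  # L success for cells p01, p11
    return out
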