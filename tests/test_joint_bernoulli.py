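"""Constructions, bounds and sampling of the bivariate Bernoulli module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from nashplat.joint_bernoulli import (
    JointBernoulliSpec,
    LatentCorrelationSpec,
    bivariate_normal_cdf,
    diagnostics_of,
    phi_bounds,
    phi_of,
    rho_to_phi,
    sample_joint,
    spec_from_direct,
    spec_from_latent_normal,
    spec_from_phi,
    spec_from_sens_spec,
)

probs_open = st.floats(0.02, 0.98)
rhos = st.floats(-0.95, 0.95)


class TestDirectSpecification:
    @pytest.mark.parametrize(
        "p00, p10, p01, p11",
        [
            (0.25, 0.25, 0.25, 0.25),
            (1.0, 0.0, 0.0, 0.0),
            (0.42, 0.18, 0.28, 0.12),
        ],
    )
    def test_fourth_cell_is_remainder(self, p00, p10, p01, p11):
        spec = spec_from_direct(p00, p10, p01)
        assert spec.p11 == pytest.approx(p11, abs=1e-12)

    def test_independence_table_has_zero_phi(self):
        # p11 = 0.12 = p1. * p.1 = 0.30 * 0.40, hence phi = 0
        spec = spec_from_direct(0.42, 0.18, 0.28)
        assert phi_of(spec) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "cells", [(-0.1, 0.5, 0.5), (0.5, 0.4, 0.2)]
    )
    def test_invalid_cells_rejected(self, cells):
        with pytest.raises(ValueError):
            spec_from_direct(*cells)

    def test_cells_must_sum_to_one(self):
        with pytest.raises(ValueError):
            JointBernoulliSpec(0.3, 0.3, 0.3, 0.2)


class TestSensSpecSpecification:
    def test_perfect_prediction(self):
        spec = spec_from_sens_spec(0.5, 1.0, 1.0)
        assert (spec.p11, spec.p00, spec.p10, spec.p01) == (0.5, 0.5, 0.0, 0.0)

    def test_worked_values(self):
        spec = spec_from_sens_spec(0.5, 0.8, 0.9)
        assert spec.p11 == pytest.approx(0.40)
        assert spec.p00 == pytest.approx(0.45)
        assert spec.p10 == pytest.approx(0.10)
        assert spec.p01 == pytest.approx(0.05)

    def test_zero_marginal_kills_s_successes(self):
        spec = spec_from_sens_spec(0.0, 0.7, 0.3)
        assert spec.p1_dot == 0.0 and spec.p11 == 0.0 and spec.p10 == 0.0

    @given(probs_open, probs_open, probs_open)
    def test_round_trip_through_diagnostics(self, p1, sens, spec_sl):
        spec = spec_from_sens_spec(p1, sens, spec_sl)
        diag = diagnostics_of(spec)
        assert diag.sens_SL == pytest.approx(sens, abs=1e-9)
        assert diag.spec_SL == pytest.approx(spec_sl, abs=1e-9)


def _phi_range_brute_force(a, b, resolution=1e-4):
    """Attainable phi by enumerating p11 over its admissible interval."""
    lo = max(0.0, a + b - 1.0)
    hi = min(a, b)
    p11 = np.arange(lo, hi + resolution / 2, resolution)
    denom = np.sqrt((1 - a) * a * (1 - b) * b)
    phi = (p11 - a * b) / denom
    return phi.min(), phi.max()


class TestPhiBounds:
    def test_symmetric_marginals_span_full_interval(self):
        assert phi_bounds(0.5, 0.5) == pytest.approx((-1.0, 1.0))

    def test_printed_formula_values(self):
        lower, upper = phi_bounds(0.3, 0.4)
        assert lower == pytest.approx(-np.sqrt(0.3 * 0.4 / (0.7 * 0.6)))
        assert upper == pytest.approx(np.sqrt((0.7 * 0.4) / (0.3 * 0.6)) ** -1)
        assert (lower, upper) == pytest.approx((-0.5345224838, 0.8017837257))

    def test_asymmetric_upper_bound_is_one_ninth(self):
        _, upper = phi_bounds(0.1, 0.9)
        assert upper == pytest.approx(1.0 / 9.0)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError):
            phi_bounds(0.0, 0.5)

    def test_brute_force_equivalence_on_grid(self):
        grid = np.arange(0.05, 0.951, 0.05)
        for a in grid:
            for b in grid:
                lower, upper = phi_bounds(a, b)
                bf_lo, bf_hi = _phi_range_brute_force(a, b)
                assert lower == pytest.approx(bf_lo, abs=2e-4)
                assert upper == pytest.approx(bf_hi, abs=2e-4)
                # bounds bracket exactly the constructible phi values
                spec_from_phi(a, b, lower + 1e-6)
                spec_from_phi(a, b, upper - 1e-6)
                with pytest.raises(ValueError):
                    spec_from_phi(a, b, upper + 1e-3)
                with pytest.raises(ValueError):
                    spec_from_phi(a, b, lower - 1e-3)


class TestPhiSpecification:
    def test_independence(self):
        assert spec_from_phi(0.5, 0.5, 0.0).p11 == pytest.approx(0.25)

    def test_printed_p11_formula(self):
        spec = spec_from_phi(0.3, 0.4, 0.7)
        expected = 0.7 * np.sqrt(0.7 * 0.3 * 0.6 * 0.4) + 0.12
        assert spec.p11 == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.277149, abs=1e-6)

    def test_out_of_bounds_phi_reports_interval(self):
        with pytest.raises(ValueError, match="attainable"):
            spec_from_phi(0.3, 0.4, 0.9)

    @given(probs_open, probs_open, st.floats(0.01, 0.99))
    def test_round_trip_and_marginals(self, a, b, frac):
        lower, upper = phi_bounds(a, b)
        phi = lower + frac * (upper - lower)
        spec = spec_from_phi(a, b, phi)
        assert spec.p1_dot == pytest.approx(a, abs=1e-9)
        assert spec.p_dot1 == pytest.approx(b, abs=1e-9)
        assert phi_of(spec) == pytest.approx(phi, abs=1e-9)


class TestLatentNormal:
    def test_independence_gives_product_table(self):
        spec = spec_from_latent_normal(LatentCorrelationSpec(0.3, 0.4, 0.0))
        assert spec.p11 == pytest.approx(0.12, abs=1e-12)
        assert spec.p00 == pytest.approx(0.42, abs=1e-12)

    def test_comonotone_limit(self):
        spec = spec_from_latent_normal(LatentCorrelationSpec(0.3, 0.3, 0.999999))
        assert spec.p11 == pytest.approx(0.3, abs=1e-3)
        assert spec.p10 == pytest.approx(0.0, abs=1e-3)

    @given(probs_open, probs_open, rhos)
    def test_marginals_recovered(self, p1, p2, rho):
        spec = spec_from_latent_normal(LatentCorrelationSpec(p1, p2, rho))
        assert spec.p1_dot == pytest.approx(p1, abs=1e-9)
        assert spec.p_dot1 == pytest.approx(p2, abs=1e-9)

    @pytest.mark.parametrize("p1, p2, rho", [(0.3, 0.4, 0.7), (0.1, 0.6, -0.4)])
    def test_quadrants_match_numerical_integration(self, p1, p2, rho):
        spec = spec_from_latent_normal(LatentCorrelationSpec(p1, p2, rho))
        zs, zl = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
        pdf = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]]).pdf
        p11, err = integrate.dblquad(
            lambda y, x: pdf([x, y]), zs, 8, zl, 8, epsabs=1e-10
        )
        assert spec.p11 == pytest.approx(p11, abs=1e-7)

    def test_quadrants_match_monte_carlo_oracle(self, rng):
        p1, p2, rho = 0.3, 0.4, 0.7
        spec = spec_from_latent_normal(LatentCorrelationSpec(p1, p2, rho))
        n = 2_000_000
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        s = z[:, 0] > stats.norm.ppf(1 - p1)
        l = z[:, 1] > stats.norm.ppf(1 - p2)
        p11_hat = (s & l).mean()
        se = np.sqrt(spec.p11 * (1 - spec.p11) / n)
        assert abs(p11_hat - spec.p11) < 4 * se

    def test_latent_cdf_matches_owens_construction(self):
        # independent check of the CDF primitive itself
        f = lambda t, h, k: np.exp(
            -(h * h - 2 * t * h * k + k * k) / (2 * (1 - t * t))
        ) / (2 * np.pi * np.sqrt(1 - t * t))
        for h, k, rho in [(0.5, -0.3, 0.6), (0.0, 1.2, -0.8), (-1.5, 2.0, 0.95)]:
            tail, _ = integrate.quad(f, 0, rho, args=(h, k), epsabs=1e-13)
            oracle = stats.norm.cdf(h) * stats.norm.cdf(k) + tail
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(oracle, abs=1e-12)


class TestDiagnostics:
    def test_perfect_agreement(self):
        diag = diagnostics_of(JointBernoulliSpec(0.5, 0.0, 0.0, 0.5))
        assert (diag.sens_SL, diag.spec_SL, diag.sens_LS, diag.spec_LS) == (
            1.0,
            1.0,
            1.0,
            1.0,
        )
        assert diag.phi == pytest.approx(1.0)

    def test_independence_conditional_equals_marginal(self):
        spec = spec_from_phi(0.3, 0.4, 0.0)
        assert diagnostics_of(spec).sens_SL == pytest.approx(0.4, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="sens_SL"):
            diagnostics_of(JointBernoulliSpec(0.6, 0.4, 0.0, 0.0))

    def test_spec_sl_attainability_bound_for_unequal_marginals(self):
        # when P(S=1) < P(L=1), spec_SL cannot reach 1 under the latent scheme
        for p1, p2 in [(0.2, 0.5), (0.3, 0.4), (0.1, 0.9)]:
            cap = (1 - p2) / (1 - p1)  # = p.0 / p0., the sharp upper bound
            assert cap < 1
            for rho in np.linspace(-0.9, 0.9, 7):
                spec = spec_from_latent_normal(LatentCorrelationSpec(p1, p2, rho))
                assert diagnostics_of(spec).spec_SL <= cap + 1e-9


class TestRhoToPhi:
    def test_zero_maps_to_zero(self):
        assert rho_to_phi(0.5, 0.5, 0.0) == 0.0

    def test_symmetric_half_marginals_reach_one(self):
        assert rho_to_phi(0.5, 0.5, 0.9999) > 0.99

    def test_matches_brute_force_integration(self):
        p1, p2, rho = 0.1, 0.6, 0.7
        zs, zl = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
        pdf = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]]).pdf
        p11, _ = integrate.dblquad(lambda y, x: pdf([x, y]), zs, 8, zl, 8)
        phi_oracle = (p11 - p1 * p2) / np.sqrt((1 - p1) * p1 * (1 - p2) * p2)
        value = rho_to_phi(p1, p2, rho)
        assert value == pytest.approx(phi_oracle, abs=1e-7)
        lower, upper = phi_bounds(p1, p2)
        assert lower < value < upper

    @pytest.mark.parametrize("p1, p2", [(0.5, 0.5), (0.3, 0.4), (0.1, 0.6)])
    def test_monotone_in_rho_and_inside_phi_bounds(self, p1, p2):
        grid = np.linspace(-0.99, 0.99, 41)
        values = [rho_to_phi(p1, p2, r) for r in grid]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        lower, upper = phi_bounds(p1, p2)
        assert all(lower - 1e-9 <= v <= upper + 1e-9 for v in values)


class TestSampling:
    def test_zero_draws(self, rng):
        spec = spec_from_phi(0.3, 0.4, 0.2)
        assert sample_joint(spec, 0, rng).shape == (0, 2)

    def test_degenerate_all_successes(self, rng):
        spec = JointBernoulliSpec(0.0, 0.0, 0.0, 1.0)
        pairs = sample_joint(spec, 100, rng)
        assert (pairs == 1).all()

    def test_law_of_large_numbers(self, rng):
        spec = spec_from_latent_normal(LatentCorrelationSpec(0.3, 0.4, 0.3))
        n = 1_000_000
        pairs = sample_joint(spec, n, rng)
        p11_hat = ((pairs[:, 0] == 1) & (pairs[:, 1] == 1)).mean()
        se = np.sqrt(spec.p11 * (1 - spec.p11) / n)
        assert abs(p11_hat - spec.p11) < 4 * se
        assert abs(pairs[:, 0].mean() - spec.p1_dot) < 4 * np.sqrt(0.3 * 0.7 / n)
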