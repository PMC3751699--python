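"""Closed-form model chain: checkpoints, identities and regime errors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import ppi_kinetics as pk
from ppi_kinetics import (DivergentTailError, KineticParameters,
                          NoSteadyStateError, NonDecayingRegimeError,
                          ShrinkingDegreeRegimeError)
from ppi_kinetics.param_estimation import feasibility

from conftest import YEAST_N


def random_valid_kp(seed: int) -> KineticParameters:
    """A feasible random rate set (log-uniform, rejection on feasibility)."""
    rng = np.random.default_rng(seed)
    while True:
        p = {
            "ki": rng.uniform(1, 20), "k2": 10 ** rng.uniform(-2, 0),
            "kXY": 10 ** rng.uniform(-2, 0), "kYX": rng.uniform(0.5, 10),
            "xi0": rng.uniform(0.05, 2), "mu": 10 ** rng.uniform(-4, -2),
            "delta_eps": rng.uniform(1, 30), "r": 10 ** rng.uniform(-2, 0),
        }
        kp = KineticParameters(f0=1.0, **p)
        if feasibility(kp)[0]:
            return kp.with_f0(pk.f0_from_steady_state(1000.0, kp))


class TestSteadyState:
    def test_essential_fraction_checkpoint(self, kp_best):
        ss = pk.steady_state(kp_best)
        assert ss.kappa == pytest.approx(0.0210, abs=5e-4)
        assert round(ss.kappa, 2) == 0.02

    def test_population_size_checkpoint(self, kp_best):
        # direct arithmetic at full precision
        assert pk.steady_state(kp_best).N_inf == pytest.approx(4135, rel=1e-3)

    def test_no_influx_means_no_essential_proteins(self):
        kp = KineticParameters(f0=100, ki=2, k2=0.1, kXY=0, kYX=3,
                               xi0=0.5, mu=0.001, delta_eps=5, r=0.1)
        ss = pk.steady_state(kp)
        assert ss.kappa == 0 and ss.Y_inf == 0

    def test_invariants(self, kp_best):
        ss = pk.steady_state(kp_best)
        assert 0 <= ss.kappa <= 1
        assert ss.Y_inf == pytest.approx(ss.kappa * ss.N_inf)
        assert ss.N_inf * ss.phi == pytest.approx(kp_best.f0, rel=1e-12)

    def test_duplication_outrunning_inactivation_is_an_error(self, kp_best):
        bad = KineticParameters(f0=1, ki=0.1, k2=0.5, kXY=0.1, kYX=1,
                                xi0=0.4, mu=0.001, delta_eps=5, r=0.1)
        with pytest.raises(NoSteadyStateError):
            pk.steady_state(bad)


class TestOriginationRate:
    def test_reference_value(self, kp_best):
        f0 = pk.f0_from_steady_state(YEAST_N, kp_best)
        assert f0 == pytest.approx(34376.8, rel=5e-3)

    def test_trivial_rates(self):
        kp = KineticParameters(f0=1, ki=1, k2=0, kXY=0, kYX=1,
                               xi0=0.5, mu=0, delta_eps=2, r=0)
        # kappa = 0 and ki - k2 = 1: f0 equals N_inf
        assert pk.f0_from_steady_state(100, kp) == pytest.approx(100)

    def test_round_trip(self, kp_best):
        ss = pk.steady_state(kp_best)
        assert pk.f0_from_steady_state(ss.N_inf, kp_best) == pytest.approx(
            kp_best.f0, rel=1e-12)


class TestSpectralDecomposition:
    def test_characteristic_times_checkpoint(self, kp_best):
        sd = pk.spectral_decomposition(kp_best)
        assert round(1 / sd.gamma1, 2) == 0.12
        assert round(1 / sd.gamma2, 2) == 0.35

    def test_block_diagonal_limit(self):
        kp = KineticParameters(f0=1, ki=2, k2=0, kXY=0, kYX=3,
                               xi0=0.5, mu=0, delta_eps=1, r=0)
        sd = pk.spectral_decomposition(kp)
        assert sorted([sd.gamma1, sd.gamma2]) == pytest.approx([2.0, 3.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generic_eigensolver(self, seed):
        kp = random_valid_kp(seed)
        sd = pk.spectral_decomposition(kp)
        matrix = np.array([[-(kp.ki - kp.k2), kp.ki],
                           [kp.kXY, -(kp.kXY + kp.kYX)]])
        evals = sorted(np.linalg.eigvals(matrix))
        assert -sd.gamma1 == pytest.approx(evals[0], rel=1e-10)
        assert -sd.gamma2 == pytest.approx(evals[1], rel=1e-10)
        assert sd.a1 + sd.a2 == pytest.approx(1.0, rel=1e-12)

    def test_non_decaying_regime_error(self):
        kp = KineticParameters(f0=1, ki=5, k2=0.1, kXY=4.9, kYX=0.001,
                               xi0=0.5, mu=0.001, delta_eps=5, r=0.1)
        with pytest.raises(NonDecayingRegimeError):
            pk.spectral_decomposition(kp)


class TestAgeDensity:
    def test_newborn_density_equals_f0(self, kp_best):
        assert pk.age_density(kp_best, 0.0) == pytest.approx(kp_best.f0)

    def test_integrates_to_population_size(self, kp_best):
        total = quad(lambda t: pk.age_density(kp_best, t), 0, np.inf)[0]
        assert total == pytest.approx(pk.steady_state(kp_best).N_inf, rel=1e-8)

    def test_monotone_decreasing(self, kp_best):
        tau = np.linspace(0, 2, 200)
        assert np.all(np.diff(pk.age_density(kp_best, tau)) < 0)


class TestDegreeKinetics:
    def test_growth_time_checkpoint(self, kp_best):
        dk = pk.degree_kinetics(kp_best, YEAST_N)
        assert round(1 / dk.v, 2) == 0.45

    def test_reference_degree_checkpoint(self, kp_best):
        dk = pk.degree_kinetics(kp_best, YEAST_N)
        assert dk.xi_r == pytest.approx(5.96, abs=0.01)
        # within the 51% SE of the fitted value 6.30779
        assert abs(dk.xi_r - 6.30779) < 0.51 * 6.30779

    def test_source_without_internal_links(self):
        kp = KineticParameters(f0=10, ki=2, k2=0.1, kXY=0.1, kYX=2,
                               xi0=1.0, mu=0.0, delta_eps=5, r=0.1)
        dk = pk.degree_kinetics(kp, 100.0)
        assert dk.g == pytest.approx(kp.f0 * kp.xi0 / 100.0)

    def test_shrinking_regime_error(self, kp_best):
        from dataclasses import replace
        with pytest.raises(ShrinkingDegreeRegimeError):
            pk.degree_kinetics(replace(kp_best, delta_eps=0.1), YEAST_N)


class TestDegreeTrajectory:
    def test_starts_at_xi0(self, kp_best):
        dk = pk.degree_kinetics(kp_best, YEAST_N)
        assert pk.degree_trajectory(dk, kp_best.xi0, 0.0) == pytest.approx(
            kp_best.xi0, rel=1e-12)

    def test_satisfies_linear_ode(self, kp_best):
        dk = pk.degree_kinetics(kp_best, YEAST_N)
        tau = np.linspace(0.05, 2.0, 40)
        h = 1e-6
        deriv = (pk.degree_trajectory(dk, kp_best.xi0, tau + h)
                 - pk.degree_trajectory(dk, kp_best.xi0, tau - h)) / (2 * h)
        expected = dk.g + dk.v * pk.degree_trajectory(dk, kp_best.xi0, tau)
        assert np.allclose(deriv, expected, rtol=1e-6)

    def test_age_inverse_identity(self, kp_best):
        dk = pk.degree_kinetics(kp_best, YEAST_N)
        tau = np.linspace(0, 3, 20)
        xi = pk.degree_trajectory(dk, kp_best.xi0, tau)
        assert np.allclose(pk.age_from_degree(dk, kp_best.xi0, xi), tau,
                           atol=1e-10)


class TestDegreeDistribution:
    def test_parameter_checkpoints(self, kp_best):
        obs = pk.degree_distribution_params(kp_best, YEAST_N)
        assert obs.beta1 == pytest.approx(4.82, abs=0.01)
        assert obs.beta2 == pytest.approx(2.26, abs=0.01)
        assert obs.A1 == pytest.approx(3.3e3, rel=0.02)
        assert obs.A2 == pytest.approx(45, rel=0.02)
        # each within the printed SE of the fitted values
        assert abs(obs.A1 - 3184.82) < 0.32 * 3184.82
        assert abs(obs.A2 - 49.8628) < 0.77 * 49.8628
        assert abs(obs.beta1 - 4.80485) < 0.29 * 4.80485
        assert abs(obs.beta2 - 2.1242) < 0.20 * 2.1242
        assert obs.eps1 == pytest.approx(0.81, abs=0.01)

    def test_beta_is_two_when_gamma_equals_v(self):
        # beta_i = gamma_i/v + 1 by construction
        kp = random_valid_kp(1)
        sd = pk.spectral_decomposition(kp)
        obs = pk.degree_distribution_params(kp, 1000.0)
        dk = pk.degree_kinetics(kp, 1000.0)
        assert obs.beta1 == pytest.approx(sd.gamma1 / dk.v + 1, rel=1e-12)
        assert obs.beta2 == pytest.approx(sd.gamma2 / dk.v + 1, rel=1e-12)

    def test_value_at_zero(self, kp_best):
        obs = pk.degree_distribution_params(kp_best, YEAST_N)
        assert pk.degree_distribution_eval(obs, 0.0) == pytest.approx(
            obs.A1 + obs.A2)

    def test_mass_conservation_by_quadrature(self, kp_best):
        obs = pk.degree_distribution_params(kp_best, YEAST_N)
        total = quad(lambda x: pk.degree_distribution_eval(obs, x),
                     kp_best.xi0, np.inf)[0]
        assert total == pytest.approx(pk.steady_state(kp_best).N_inf, rel=1e-6)

    def test_small_degree_approximation(self, kp_best):
        obs = pk.degree_distribution_params(kp_best, YEAST_N)
        xi = obs.xi_r * 0.01
        full = pk.degree_distribution_eval(obs, xi)
        approx = pk.double_exponential_approx(obs, xi)
        assert abs(approx / full - 1) < 0.01

    def test_double_exponential_shares_origin(self, kp_best):
        obs = pk.degree_distribution_params(kp_best, YEAST_N)
        assert pk.double_exponential_approx(obs, 0.0) == pytest.approx(
            pk.degree_distribution_eval(obs, 0.0))
        assert pk.double_exponential_approx(obs, 1e-6) == pytest.approx(
            pk.degree_distribution_eval(obs, 1e-6), rel=1e-5)

    def test_eps_from_fitted_values(self):
        assert 4.80485 / 6.30779 == pytest.approx(0.762, abs=1e-3)


class TestLinkLaw:
    def test_probability_checkpoints(self, kp_best):
        p1, p2 = pk.link_probabilities(kp_best, YEAST_N)
        assert p1 == pytest.approx(0.737, abs=0.002)
        assert p2 == pytest.approx(5.53e-4, rel=0.01)
        assert abs(p1 / 0.73526 - 1) < 0.005
        assert abs(p2 / 0.000552383 - 1) < 0.005

    def test_no_pairwise_channel_means_no_quadratic_term(self):
        kp = KineticParameters(f0=10, ki=4, k2=0.1, kXY=0.05, kYX=2,
                               xi0=0.5, mu=0.0, delta_eps=5, r=0.1)
        _, p2 = pk.link_probabilities(kp, 500.0)
        assert p2 == 0.0

    def test_total_links_trivial(self):
        assert pk.total_links(0, 0, 100) == 0
        assert pk.total_links(0.7, 1e-4, 1) == pytest.approx(0.7)

    def test_yeast_prediction(self):
        L = pk.total_links(0.73526, 0.000552383, YEAST_N)
        assert L == pytest.approx(7762, abs=1)  # observed 7839, within residual

    def test_divergent_tail_error(self):
        kp = KineticParameters(f0=1, ki=4, k2=0.1, kXY=0.05, kYX=2,
                               xi0=0.5, mu=0.001, delta_eps=30, r=0.1)
        dk = pk.degree_kinetics(kp, 500.0)
        sd = pk.spectral_decomposition(kp)
        assert sd.gamma2 / dk.v + 1 <= 2  # preference too strong
        with pytest.raises(DivergentTailError):
            pk.link_probabilities(kp, 500.0)


class TestInvariantsAcrossParameterSpace:
    """Identities that must hold for every valid rate set."""

    @pytest.mark.parametrize("seed", range(8))
    def test_mass_conservation_identity(self, seed):
        kp = random_valid_kp(seed)
        sd = pk.spectral_decomposition(kp)
        ss = pk.steady_state(kp)
        assert kp.f0 * (sd.a1 / sd.gamma1 + sd.a2 / sd.gamma2) == pytest.approx(
            ss.N_inf, rel=1e-10)
        assert ss.N_inf * ss.phi == pytest.approx(kp.f0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_change_of_variables_consistency(self, seed):
        # the degree density is the age density pushed through xi(tau)
        kp = random_valid_kp(seed)
        N = pk.steady_state(kp).N_inf
        obs = pk.degree_distribution_params(kp, N)
        dk = pk.degree_kinetics(kp, N)
        xi = np.array([0.1, 0.5, 1.0, 3.0, 10.0, 40.0]) * dk.xi_r
        tau = pk.age_from_degree(dk, kp.xi0, xi + kp.xi0 * 0)
        # only ages >= 0 (degrees above the newborn degree) are in range
        ok = tau >= 0
        dtau_dxi = 1.0 / (dk.g + dk.v * (xi[ok]))
        via_age = pk.age_density(kp, tau[ok]) * dtau_dxi
        direct = pk.degree_distribution_eval(obs, xi[ok])
        assert np.allclose(via_age, direct, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_link_law_equals_quadrature(self, seed):
        kp = random_valid_kp(seed)
        N = pk.steady_state(kp).N_inf
        obs = pk.degree_distribution_params(kp, N)
        p1, p2 = pk.link_probabilities(kp, N)
        closed = pk.total_links(p1, p2, N)
        quadrature = 0.5 * quad(
            lambda x: x * pk.degree_distribution_eval(obs, x),
            kp.xi0, np.inf, limit=200)[0]
        assert closed == pytest.approx(quadrature, rel=1e-4)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_spectral_invariants_property(self, seed):
        kp = random_valid_kp(seed)
        sd = pk.spectral_decomposition(kp)
        assert sd.gamma1 >= sd.gamma2 > 0
        assert sd.a1 + sd.a2 == pytest.approx(1.0, rel=1e-9)
        dk = pk.degree_kinetics(kp, 1000.0)
        assert 0 < dk.w < 1
        assert dk.xi_r == pytest.approx(dk.g / dk.v, rel=1e-12)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        KineticParameters(f0=-1, ki=1, k2=0, kXY=0.1, kYX=1,
                          xi0=0.5, mu=0, delta_eps=1, r=0)
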