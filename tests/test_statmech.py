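import math

import numpy as np
import pytest
from scipy import integrate

from leupsim.model import Domain, ModelParams, ParticleState
from leupsim.neighbors import build_neighbor_index
from leupsim.statmech import (
    angular_entropy,
    angular_entropy_gradient,
    angular_entropy_gradients,
    classify_entropy_extrema,
    gamma_from_polar_order,
    helmholtz_free_energy,
    neighborhood_stats,
    speed_entropy,
    speed_entropy_gradients,
    wrapped_cauchy_pdf,
)

from conftest import random_state


def quad_entropy_circular(pdf):
    """Quadrature differential entropy of a circular density."""
    val, _ = integrate.quad(lambda x: -pdf(x) * math.log(pdf(x)), 0, 2 * math.pi, limit=200)
    return val


class TestWrappedCauchy:
    def test_normalizes_to_one(self):
        for gamma in (0.1, 0.5, 1.0, 2.0, 5.0):
            val, _ = integrate.quad(
                lambda x: wrapped_cauchy_pdf(x, 1.3, gamma), 0, 2 * math.pi, limit=200
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_peak_value_at_mean(self):
        expected = math.sinh(1.0) / (2 * math.pi * (math.cosh(1.0) - 1.0))
        assert wrapped_cauchy_pdf(0.7, 0.7, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.3444, abs=5e-4)

    def test_large_gamma_approaches_uniform(self):
        grid = np.linspace(0, 2 * math.pi, 9)
        assert np.allclose(wrapped_cauchy_pdf(grid, 0.0, 40.0), 1 / (2 * math.pi), atol=1e-8)

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            wrapped_cauchy_pdf(0.0, 0.0, 0.0)


class TestEntropyClosedForms:
    @pytest.mark.parametrize("gamma", [0.1, 0.5, 1.0, 2.0, 5.0])
    def test_angular_entropy_matches_quadrature(self, gamma):
        quad = quad_entropy_circular(lambda x: wrapped_cauchy_pdf(x, 0.0, gamma))
        assert angular_entropy(gamma) == pytest.approx(quad, abs=1e-6)

    def test_angular_entropy_known_values(self):
        assert angular_entropy(math.log(2)) == pytest.approx(
            math.log(2 * math.pi) + math.log(0.75), rel=1e-12
        )
        assert angular_entropy(50.0) == pytest.approx(math.log(2 * math.pi), abs=1e-12)
        assert angular_entropy(0.01) < -2.0

    def test_angular_entropy_monotone_in_gamma(self):
        g = np.linspace(0.05, 6, 60)
        assert np.all(np.diff(angular_entropy(g)) > 0)

    @pytest.mark.parametrize("sigma_sq", [0.1, 1.0, 4.0])
    def test_speed_entropy_matches_quadrature(self, sigma_sq):
        def pdf(v):
            return math.sqrt(2 / (sigma_sq * math.pi)) * math.exp(-v * v / (2 * sigma_sq))

        upper = 40 * math.sqrt(sigma_sq)  # tail beyond is below double precision
        val, _ = integrate.quad(
            lambda v: -pdf(v) * math.log(max(pdf(v), 1e-300)), 0, upper, limit=200
        )
        assert speed_entropy(sigma_sq) == pytest.approx(val, abs=1e-6)

    def test_speed_entropy_known_values(self):
        assert speed_entropy(2 / math.pi) == pytest.approx(0.5, rel=1e-12)
        assert speed_entropy(2.0) == pytest.approx(0.5 * math.log(math.pi) + 0.5, rel=1e-12)
        with pytest.raises(ValueError):
            speed_entropy(0.0)

    def test_entropies_reject_invalid_domain(self):
        with pytest.raises(ValueError):
            angular_entropy(-1.0)
        with pytest.raises(ValueError):
            speed_entropy(-2.0)


class TestGammaFromPolarOrder:
    def test_inverse_of_exponential(self):
        assert gamma_from_polar_order(math.exp(-1)) == pytest.approx(1.0, rel=1e-9)
        assert gamma_from_polar_order(0.5) == pytest.approx(math.log(2), rel=1e-12)

    def test_clipping_keeps_result_finite(self):
        assert gamma_from_polar_order(1.0, 1e-6) == pytest.approx(1e-6, rel=1e-3)
        assert gamma_from_polar_order(0.0, 1e-6) == pytest.approx(-math.log(1e-6))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            gamma_from_polar_order(1.2)


class TestNeighborhoodStats:
    def _three_agents(self, thetas, speeds=None):
        pos = np.array([[5.0, 5.0], [5.5, 5.0], [5.0, 5.5]])
        speeds = np.ones(3) if speeds is None else np.asarray(speeds, float)
        return ParticleState(0.0, pos, np.asarray(thetas, float), speeds)

    def test_identical_neighbors_give_clipped_gamma(self, domain, params):
        state = self._three_agents([0.0, 0.0, 0.0])
        idx = build_neighbor_index(state, 2.0, domain)
        stats = neighborhood_stats(state, 0, idx, params)
        assert stats.s1_local == pytest.approx(1 - params.s1_clip)
        assert stats.theta_bar == pytest.approx(0.0)
        assert stats.gamma == pytest.approx(-math.log(1 - params.s1_clip))

    def test_cancelling_neighbors(self, domain, params):
        state = self._three_agents([0.0, math.pi, 0.0])
        # agent 0 at theta=0 with neighbors {pi, 0}: vbar cancels
        idx = build_neighbor_index(state, 2.0, domain)
        stats = neighborhood_stats(state, 0, idx, params)
        assert stats.vbar_x == pytest.approx(-1.0 + 1.0)
        # local S1 over {0, pi, 0} = 1/3
        assert stats.s1_local == pytest.approx(1 / 3)

    def test_matches_brute_force_moments(self, rng, domain, params):
        state = random_state(rng, 50, domain.L)
        idx = build_neighbor_index(state, 6.0, domain)
        for n in (0, 17, 42):
            nb = idx.neighbors(n)
            stats = neighborhood_stats(state, n, idx, params)
            z = np.exp(1j * state.orientations[np.append(nb, n)])
            assert stats.s1_local == pytest.approx(abs(z.mean()), rel=1e-9)
            assert stats.sigma_sq == pytest.approx(
                (state.speeds[np.append(nb, n)] ** 2).mean(), rel=1e-9
            )


class TestEntropyGradients:
    def _entropy_of_focal_heading(self, state, n, idx, params, x):
        theta = state.orientations.copy()
        theta[n] = x % (2 * math.pi)
        nb = idx.neighbors(n)
        z = np.exp(1j * theta[np.append(nb, n)])
        s1 = np.clip(abs(z.mean()), params.s1_clip, 1 - params.s1_clip)
        return angular_entropy(-math.log(s1))

    def test_zero_at_parallel_and_antiparallel(self, domain, params):
        pos = np.array([[5.0, 5.0], [5.5, 5.0], [5.0, 5.5]])
        for focal in (0.0, math.pi):
            state = ParticleState(0.0, pos, np.array([focal, 0.0, 0.0]), np.ones(3))
            idx = build_neighbor_index(state, 2.0, domain)
            grad = angular_entropy_gradient(state, 0, idx, params)
            assert grad == pytest.approx(0.0, abs=1e-12)

    def test_isolated_agent_zero_gradient(self, params):
        dom = Domain(L=30.0)
        state = ParticleState(
            0.0, np.array([[1.0, 1.0], [25.0, 25.0]]), np.array([0.3, 2.0]), np.ones(2)
        )
        idx = build_neighbor_index(state, 3.0, dom)
        assert angular_entropy_gradient(state, 0, idx, params) == 0.0

    def test_angular_gradient_matches_finite_difference(self, rng, domain, params):
        h = 1e-6
        checked = 0
        while checked < 100:
            n_ag = int(rng.integers(3, 40))
            state = random_state(rng, n_ag, domain.L)
            idx = build_neighbor_index(state, 5.0, domain)
            grads = angular_entropy_gradients(state, idx, params)
            n = int(rng.integers(0, n_ag))
            if len(idx.neighbors(n)) == 0:
                continue
            fd = (
                self._entropy_of_focal_heading(state, n, idx, params, state.orientations[n] + h)
                - self._entropy_of_focal_heading(state, n, idx, params, state.orientations[n] - h)
            ) / (2 * h)
            if abs(fd) < 1e-8:
                continue
            assert grads[n] == pytest.approx(fd, rel=1e-5)
            checked += 1

    def test_speed_gradient_matches_finite_difference(self, rng, domain, params):
        h = 1e-6
        checked = 0
        while checked < 100:
            n_ag = int(rng.integers(3, 40))
            state = random_state(rng, n_ag, domain.L, speed_high=2.0)
            idx = build_neighbor_index(state, 5.0, domain)
            grads = speed_entropy_gradients(state, idx, params)
            n = int(rng.integers(0, n_ag))
            if state.speeds[n] < 1e-3:
                continue

            def S(v):
                nb = idx.neighbors(n)
                sq = np.append(state.speeds[nb], v) ** 2
                return speed_entropy(sq.mean())

            fd = (S(state.speeds[n] + h) - S(state.speeds[n] - h)) / (2 * h)
            assert grads[n] == pytest.approx(fd, rel=1e-5)
            checked += 1

    def test_single_sample_speed_gradient_is_inverse_speed(self, params):
        dom = Domain(L=30.0)
        state = ParticleState(
            0.0, np.array([[1.0, 1.0], [25.0, 25.0]]), np.array([0.0, 0.0]),
            np.array([2.0, 1.0]),
        )
        idx = build_neighbor_index(state, 3.0, dom)
        # isolated: sigma^2 = v^2, N_A = 1 -> dS/dv = 1/v
        assert speed_entropy_gradients(state, idx, params)[0] == pytest.approx(0.5)

    def test_zero_speed_zero_gradient(self, params):
        dom = Domain(L=30.0)
        state = ParticleState(
            0.0, np.array([[1.0, 1.0], [1.5, 1.0]]), np.array([0.0, 0.0]),
            np.array([0.0, 1.0]),
        )
        idx = build_neighbor_index(state, 3.0, dom)
        assert speed_entropy_gradients(state, idx, params)[0] == 0.0


class TestEntropyExtrema:
    def test_identical_neighbor_headings(self, domain, params):
        pos = np.array([[5.0, 5.0], [5.5, 5.0], [5.0, 5.5], [5.5, 5.5]])
        theta = np.array([1.0, np.pi / 3, np.pi / 3, np.pi / 3])
        state = ParticleState(0.0, pos, theta, np.ones(4))
        idx = build_neighbor_index(state, 2.0, domain)
        stats = neighborhood_stats(state, 0, idx, params)
        t_min, t_max = classify_entropy_extrema(stats)
        assert t_min == pytest.approx(np.pi / 3)
        assert t_max == pytest.approx(np.pi / 3 + np.pi)

    def test_cancellation_raises(self, domain, params):
        pos = np.array([[5.0, 5.0], [5.5, 5.0], [4.5, 5.0]])
        state = ParticleState(0.0, pos, np.array([1.0, 0.0, np.pi]), np.ones(3))
        idx = build_neighbor_index(state, 2.0, domain)
        stats = neighborhood_stats(state, 0, idx, params)
        with pytest.raises(ValueError, match="mean orientation"):
            classify_entropy_extrema(stats)

    def test_agrees_with_grid_scan(self, rng, domain, params):
        # exhaustive scan oracle: argmin at theta_bar, argmax at theta_bar + pi
        grid = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        cell = grid[1] - grid[0]
        for _ in range(20):
            n_nb = int(rng.integers(2, 30))
            nb_theta = rng.uniform(0, 2 * np.pi, n_nb)
            z_nb = np.exp(1j * nb_theta).sum()
            if abs(z_nb) < 1e-3:
                continue
            s1 = np.abs(z_nb + np.exp(1j * grid)) / (n_nb + 1)
            entropy = angular_entropy(
                gamma_from_polar_order(np.minimum(s1, 1 - 1e-6), 1e-6)
            )
            theta_bar = math.atan2(z_nb.imag, z_nb.real) % (2 * math.pi)
            argmin = grid[np.argmin(entropy)]
            argmax = grid[np.argmax(entropy)]

            def circ_dist(a, b):
                d = abs(a - b) % (2 * math.pi)
                return min(d, 2 * math.pi - d)

            assert circ_dist(argmin, theta_bar) <= cell
            assert circ_dist(argmax, (theta_bar + math.pi) % (2 * math.pi)) <= cell


class TestHelmholtzFreeEnergy:
    def test_invalid_at_and_above_one(self):
        for beta in (1.0, 1.5, 10.0):
            res = helmholtz_free_energy(beta, 1.0)
            assert not res.valid
            assert math.isnan(res.value)

    def test_valid_strictly_below_one(self):
        grid = np.linspace(-5, 0.999, 101)
        for beta in grid:
            res = helmholtz_free_energy(float(beta), 1.0)
            assert res.valid and math.isfinite(res.value)

    def test_known_values(self):
        assert helmholtz_free_energy(-1.0, 1.0, 1).value == pytest.approx(
            math.log(4 * math.pi) - math.log(2), rel=1e-12
        )
        assert helmholtz_free_energy(0.5, 1.0, 1).value == pytest.approx(
            math.log(4 * math.pi) + math.log(0.5) / 0.5, rel=1e-12
        )

    def test_zero_sensitivity_analytic_limit(self):
        # at gamma_n = 1 the divergent gamma coefficient drops out and the
        # beta -> 0 limit exists: ln(4 pi) - 1
        res0 = helmholtz_free_energy(0.0, 1.0)
        eps = helmholtz_free_energy(1e-9, 1.0)
        assert res0.valid
        assert res0.value == pytest.approx(eps.value, abs=1e-6)
        assert res0.value == pytest.approx(math.log(4 * math.pi) - 1.0, rel=1e-12)
        # away from gamma_n = 1 the regularized value stays finite
        assert math.isfinite(helmholtz_free_energy(0.0, 2.0).value)

    def test_extensive_in_cell_count(self):
        one = helmholtz_free_energy(0.3, 1.5, 1)
        many = helmholtz_free_energy(0.3, 1.5, 7)
        assert many.value == pytest.approx(7 * one.value, rel=1e-12)

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            helmholtz_free_energy(0.5, 0.0)
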