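"""Exact stochastic simulation: reproducibility, burst statistics and
convergence to the FSP law."""

import numpy as np
import pytest

from holimap.analysis import hellinger
from holimap.linear_solver import fsp_steady
from holimap.model import compile_reactions
from holimap.ssa import (
    SSAError,
    empirical_distribution,
    sample_conditional_moments,
    sample_geometric_burst,
    simulate_ensemble,
)
from holimap.moments import derive_moment_system, integrate_moments, ConditionalMomentState
from tests.test_moments import telegraph_network


class TestGeometricBursts:
    def test_p_zero_always_zero(self, rng):
        assert all(sample_geometric_burst(0.0, rng) == 0 for _ in range(100))

    @pytest.mark.parametrize("p,mean", [(0.5, 1.0), (0.75, 3.0)])
    def test_sample_mean(self, p, mean, rng):
        draws = np.array([sample_geometric_burst(p, rng) for _ in range(200_000)])
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - mean) < 3 * se

    def test_invalid_parameter(self, rng):
        with pytest.raises(SSAError):
            sample_geometric_burst(1.0, rng)


class TestEnsembles:
    def test_bitwise_reproducibility(self):
        system = compile_reactions(telegraph_network())
        t = np.linspace(0, 5, 6)
        a = simulate_ensemble(system, 50, t, seed=7)
        b = simulate_ensemble(system, 50, t, seed=7)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_ensemble(system, 50, t, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_constitutive_bursty_mean(self):
        # rho = 2, B = 3, d = 1 -> stationary mean 6
        system = compile_reactions(
            telegraph_network(sigma_b=1.0, sigma_u=1e-9, rho0=2.0, rho1=2.0,
                              d=1.0, p=0.75)
        )
        ens = simulate_ensemble(system, 10_000, np.linspace(0, 12, 4), seed=3)
        final = ens.counts[:, -1, system.protein_of_gene[0]]
        se = final.std() / np.sqrt(len(final))
        assert abs(final.mean() - 6.0) < 3 * se

    def test_distribution_converges_to_fsp(self):
        system = compile_reactions(telegraph_network())
        ens = simulate_ensemble(system, 100_000, np.linspace(0, 15, 4), seed=5)
        emp = empirical_distribution(ens, "P1", 15.0)
        ref = fsp_steady(dict(sigma_b=1.0, sigma_u=1.0, rho0=0.0, rho1=10.0,
                              d=1.0, p=0.0))
        assert hellinger(emp, ref.normalized()) < 0.02

    def test_error_decreases_with_ensemble_size(self):
        system = compile_reactions(telegraph_network())
        ref = fsp_steady(dict(sigma_b=1.0, sigma_u=1.0, rho0=0.0, rho1=10.0,
                              d=1.0, p=0.0)).normalized()
        t = np.linspace(0, 15, 4)
        hds = []
        for n, seed in ((1000, 11), (4000, 12), (16000, 13)):
            ens = simulate_ensemble(system, n, t, seed=seed)
            hds.append(hellinger(empirical_distribution(ens, "P1", 15.0), ref))
        assert hds[2] < hds[0]  # N^{-1/2} trend within sampling noise

    def test_decreasing_grid_rejected(self):
        system = compile_reactions(telegraph_network())
        with pytest.raises(SSAError, match="increasing"):
            simulate_ensemble(system, 5, [0.0, 2.0, 1.0], seed=0)


class TestEmpiricalSummaries:
    def test_single_trajectory_is_point_mass(self):
        system = compile_reactions(telegraph_network())
        ens = simulate_ensemble(system, 1, np.linspace(0, 3, 4), seed=2)
        d = empirical_distribution(ens, "P1", 3.0)
        assert d.probs.max() == pytest.approx(1.0)
        assert d.probs.sum() == pytest.approx(1.0)

    def test_unknown_species_rejected(self):
        system = compile_reactions(telegraph_network())
        ens = simulate_ensemble(system, 3, [0.0, 1.0], seed=2)
        with pytest.raises(KeyError):
            empirical_distribution(ens, "XYZ", 1.0)

    def test_conditional_moments_closed_form_case(self):
        """All trajectories in state 0 with n = 3: g0 = 1, mu_{1,0} = 3,
        mu_{2,0} = 6 (falling factorial 3*2)."""
        net = telegraph_network(sigma_b=0.0, sigma_u=0.0, rho0=0.0, rho1=0.0, d=0.0)
        system = compile_reactions(net)
        x0 = system.initial_counts()
        x0[system.protein_of_gene[0]] = 3
        ens = simulate_ensemble(system, 10, [0.0, 1.0], seed=0, init=x0)
        st = sample_conditional_moments(ens, 0, 1.0, order=2)
        assert st.g(0) == 1.0 and st.g(1) == 0.0
        assert st.mu((1,), 0) == pytest.approx(3.0)
        assert st.mu((2,), 0) == pytest.approx(6.0)

    def test_order_zero_returns_frequencies(self):
        system = compile_reactions(telegraph_network())
        ens = simulate_ensemble(system, 500, [0.0, 4.0], seed=9)
        st = sample_conditional_moments(ens, 0, 4.0, order=0)
        assert st.g(0) + st.g(1) == pytest.approx(1.0)

    def test_sample_moments_match_moment_odes(self):
        system = compile_reactions(telegraph_network())
        t_grid = np.linspace(0, 3, 4)
        ens = simulate_ensemble(system, 20_000, t_grid, seed=17)
        ms = derive_moment_system(telegraph_network(), K=2)
        states = integrate_moments(ms, ConditionalMomentState.initial(ms.basis), t_grid)
        st = sample_conditional_moments(ens, 0, 3.0, order=1)
        n = ens.at(3.0)[:, system.protein_of_gene[0]]
        se = n.std() / np.sqrt(len(n))
        exact = states[-1]
        assert abs(st.g(1) - exact.g(1)) < 3 * 0.5 / np.sqrt(ens.n_traj) + 1e-3
        assert abs(st.mu((1,), 0) + st.mu((1,), 1) - exact.expect({0: 1})) < 3 * se
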