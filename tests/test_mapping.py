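"""Moment-matching equations and the self-consistent closure solve."""

import numpy as np
import pytest

from holimap.analysis import hellinger
from holimap.linear_solver import fsp_nonlinear
from holimap.mapping import (
    MappingError,
    Matcher,
    hm2_params,
    hm4_params,
    hm3_params,
    holimap_solve,
    lma_params,
)
from holimap.model import (
    GeneNetwork,
    GeneSpec,
    build_autoreg,
    build_fixture,
    compile_reactions,
)
from holimap.moments import ConditionalMomentState


def autoreg(**kw):
    base = dict(sigma_b=0.1, sigma_u=1.0, rho_b=50.0, rho_u=5.0, d=1.0, h=1, p=0.5)
    base.update(kw)
    return build_autoreg(**base)


def linear_net():
    return GeneNetwork(
        (GeneSpec(0, alpha0=0.7, alpha1=1.3, rho0=1.0, rho1=8.0, d=1.0),), ()
    )


class TestLMA:
    def test_effective_rate_is_conditional_mean_flux(self):
        # sigma_b mu_{1,0} / g_0 = 0.1 * 2 / 0.5 = 0.4
        st = ConditionalMomentState.single_gene(0.5, 0.5, {(1, 0): 2.0, (1, 1): 4.0})
        assert lma_params(st, autoreg())[0].sigma_b == pytest.approx(0.4)

    def test_zero_conditional_mean_gives_zero_rate(self):
        st = ConditionalMomentState.single_gene(0.5, 0.5, {(1, 0): 0.0, (1, 1): 4.0})
        assert lma_params(st, autoreg())[0].sigma_b == 0.0

    def test_cooperative_rate_uses_falling_factorial_mean(self):
        # Poisson(lambda) factorial moments: E[(n)_m] = lambda^m, so for
        # h = 2 the effective rate is sigma_b * lambda^2
        lam = 4.0
        st = ConditionalMomentState.single_gene(
            0.5, 0.5,
            {(m, s): 0.5 * lam**m for m in (1, 2, 3) for s in (0, 1)},
        )
        net = autoreg(h=2)
        assert lma_params(st, net)[0].sigma_b == pytest.approx(0.1 * lam**2)

    def test_vanishing_unbound_state_raises(self):
        st = ConditionalMomentState.single_gene(0.0, 1.0, {(1, 0): 0.0, (1, 1): 4.0})
        with pytest.raises(MappingError, match="vanishes"):
            lma_params(st, autoreg())


class TestHM2:
    def test_two_by_two_solution(self):
        # independently solved 2x2: (sigma_u~, sigma_b~) = (1.1, 0.5)
        st = ConditionalMomentState.single_gene(
            0.5, 0.5, {(1, 0): 2.0, (1, 1): 4.0, (2, 0): 6.0, (2, 1): 0.0}
        )
        p = hm2_params(st, autoreg(sigma_u=1.0, sigma_b=0.1))[0]
        assert (p.sigma_u, p.sigma_b) == (pytest.approx(1.1), pytest.approx(0.5))

    def test_no_feedback_forces_identity(self):
        st = ConditionalMomentState.single_gene(
            0.5, 0.5, {(1, 0): 2.0, (1, 1): 4.0, (2, 0): 6.0, (2, 1): 9.0}
        )
        p = hm2_params(st, autoreg(sigma_b=0.0))[0]
        assert p.sigma_u == pytest.approx(1.0)
        assert p.sigma_b == pytest.approx(0.0, abs=1e-12)

    def test_equal_conditional_means_fall_back(self):
        # mu10/g0 = mu11/g1 makes the matching singular -> LMA fallback
        st = ConditionalMomentState.single_gene(
            0.5, 0.5, {(1, 0): 2.0, (1, 1): 2.0, (2, 0): 5.0, (2, 1): 5.0}
        )
        p = hm2_params(st, autoreg())[0]
        assert "singular-matching" in p.flags
        assert p.sigma_u == pytest.approx(1.0)  # LMA keeps sigma_u

    def test_identity_on_linear_network(self):
        st = ConditionalMomentState.single_gene(
            0.6, 0.4, {(1, 0): 1.0, (1, 1): 3.0, (2, 0): 2.0, (2, 1): 10.0}
        )
        p = hm2_params(st, linear_net())[0]
        assert p.sigma_b == pytest.approx(0.7)
        assert p.sigma_u == pytest.approx(1.3)


class TestHM4:
    def test_identity_on_linear_network(self):
        st = ConditionalMomentState.single_gene(
            0.6, 0.4, {(1, 0): 1.0, (1, 1): 3.0, (2, 0): 2.0, (2, 1): 10.0}
        )
        p = hm4_params(st, linear_net())[0]
        assert p.sigma_b == pytest.approx(0.7)
        assert p.sigma_u == pytest.approx(1.3)
        assert p.rho0 == pytest.approx(1.0)
        assert p.rho1 == pytest.approx(8.0)

    def test_fixed_point_self_consistency(self):
        """Re-matching from the converged closure moments reproduces the
        returned parameters."""
        net = autoreg(sigma_b=0.02, sigma_u=2.0)
        sol = holimap_solve(net, "hm4", "steady")
        again = hm4_params(sol.moments, net, clamp_negative=True)[0]
        p = sol.params[0]
        assert again.sigma_b == pytest.approx(p.sigma_b, rel=1e-6)
        assert again.sigma_u == pytest.approx(p.sigma_u, rel=1e-6)
        assert again.rho0 == pytest.approx(p.rho0, rel=1e-6)
        assert again.rho1 == pytest.approx(p.rho1, rel=1e-6)

    def test_negative_parameters_flagged_not_silent(self):
        """When the matched rates leave the physical region the solver
        must either raise or clamp with an explicit flag."""
        from holimap.mapping import NegativeParameterError

        st = ConditionalMomentState.single_gene(
            0.9, 0.1, {(1, 0): 30.0, (1, 1): 0.1, (2, 0): 1000.0, (2, 1): 0.01}
        )
        net = autoreg(sigma_b=5.0, sigma_u=50.0)
        try:
            ps = hm4_params(st, net, clamp_negative=False)
        except NegativeParameterError:
            ps = hm4_params(st, net, clamp_negative=True)
            flat = tuple(f for p in ps for f in p.flags)
            assert "clamped-negative" in flat or "singular-matching" in flat
        else:
            assert all(min(p.sigma_b, p.sigma_u, p.rho0, p.rho1) >= 0 for p in ps)


class TestHM3:
    def test_no_enzymatic_channel_keeps_decay(self):
        system = build_fixture("mrna_degradation_control", alpha=0.0)
        counts = np.tile(system.initial_counts(), (4, 1))
        counts[:, system.protein_of_gene[0]] = [5, 10, 15, 10]
        p = hm3_params(counts, system)[0]
        assert p.d == pytest.approx(0.5)

    def test_product_moment_loss_matching(self):
        """d~ = d + alpha E[n_M n_E*] / E[n_M] for the enzymatic channel:
        independent levels with E[n_M] = 10, E[n_E*] = 4 give 1.8."""
        system = build_fixture("mrna_degradation_control", alpha=0.2, d=1.0)
        Mi = system.protein_of_gene[0]
        Es = system.species_index("E*")
        counts = np.tile(system.initial_counts(), (4, 1))
        counts[:, Mi] = [8, 8, 12, 12]
        counts[:, Es] = [2, 6, 2, 6]
        p = hm3_params(counts, system)[0]
        assert p.d == pytest.approx(1.0 + 0.2 * 40.0 / 10.0)

    def test_sequestration_linear_model_matches_ssa_mean(self):
        from holimap.hybrid import hybrid_solve
        from holimap.ssa import simulate_ensemble

        system = build_fixture("sequestration")
        t_grid = np.linspace(0.0, 30.0, 61)
        res = hybrid_solve(system, "hm3", N=600, t_grid=t_grid, seed=5,
                           mode="steady", genes=[0], steady_window=0.5)
        big = simulate_ensemble(system, 4000, np.linspace(0.0, 30.0, 7), seed=99)
        p1 = system.protein_of_gene[0]
        ssa_mean = big.counts[:, -1, p1].mean()
        se = big.counts[:, -1, p1].std() / np.sqrt(big.n_traj)
        assert abs(res.distributions[0].mean() - ssa_mean) < max(3 * se, 0.05 * ssa_mean)


class TestHolimapSolve:
    def test_no_feedback_reduces_to_direct_fsp(self):
        net = autoreg(sigma_b=0.0)
        sol = holimap_solve(net, "hm2", "steady")
        ref = fsp_nonlinear(compile_reactions(net), network=net)
        assert hellinger(sol.distributions[0].normalized(), ref.normalized()) < 1e-6

    def test_steady_accuracy_easy_regime(self):
        net = autoreg(sigma_b=0.02, sigma_u=2.0)
        ref = fsp_nonlinear(compile_reactions(net), network=net).normalized()
        for method, tol in (("lma", 0.25), ("hm2", 0.08), ("hm4", 0.08)):
            sol = holimap_solve(net, method, "steady")
            assert hellinger(sol.distributions[0].normalized(), ref) < tol

    def test_hm3_requires_hybrid(self):
        with pytest.raises(MappingError, match="hybrid"):
            holimap_solve(autoreg(), "hm3", "steady")

    def test_transient_records_parameter_trajectories(self):
        net = autoreg(sigma_b=0.02, sigma_u=2.0)
        t_grid = np.linspace(0.0, 4.0, 9)
        sol = holimap_solve(net, "hm2", "transient", t_grid=t_grid)
        tr = sol.params[0]
        assert len(tr.times) == len(t_grid)
        assert len(sol.distributions[0]) == len(t_grid)
        # matched rates become non-trivial once moments grow
        assert tr.sigma_b[-1] > 0

    def test_transient_matches_ssa_mean(self):
        from holimap.ssa import simulate_ensemble

        net = autoreg(sigma_b=0.02, sigma_u=2.0)
        t_grid = np.linspace(0.0, 5.0, 11)
        sol = holimap_solve(net, "hm2", "transient", t_grid=t_grid)
        system = compile_reactions(net)
        ens = simulate_ensemble(system, 4000, t_grid, seed=21)
        prot = system.protein_of_gene[0]
        for k in (4, 10):
            ssa_mean = ens.counts[:, k, prot].mean()
            se = ens.counts[:, k, prot].std() / np.sqrt(ens.n_traj)
            assert abs(sol.distributions[0][k].mean() - ssa_mean) < 4 * se + 0.3


class TestMatcherStructure:
    def test_lma_is_hm2_with_frozen_unbinding(self):
        """Replacing the second matching equation by sigma_u~ = sigma_u
        reproduces the LMA rate (structural cross-check of the matching equations)."""
        st = ConditionalMomentState.single_gene(
            0.4, 0.6, {(1, 0): 2.0, (1, 1): 5.0, (2, 0): 7.0, (2, 1): 1.0}
        )
        net = autoreg(sigma_b=0.3, sigma_u=2.0)
        m = Matcher(net, "hm2")
        # first matching equation with sigma_u~ frozen at sigma_u:
        # sigma_b~ = (sigma_u g1 - flux0) / g0  with flux0 = eval(b0)
        flux0 = st.eval_terms(m.b0[0])
        sb = (2.0 * st.g_gene(0, 1) - flux0) / st.g_gene(0, 0)
        assert sb == pytest.approx(lma_params(st, net)[0].sigma_b)
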