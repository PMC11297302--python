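"""Moment-equation derivation checked against hand algebra and a
brute-force truncated-CME generator."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from holimap import _ffpoly as ff
from holimap.model import (
    GeneNetwork,
    GeneSpec,
    build_autoreg,
    compile_reactions,
)
from holimap.moments import (
    ConditionalMomentState,
    MomentError,
    derive_moment_system,
    integrate_moments,
    rhs_oracle_check,
    steady_state_moments,
)


def telegraph_network(sigma_b=1.0, sigma_u=1.0, rho0=0.0, rho1=10.0, d=1.0, p=0.0):
    return GeneNetwork(
        (GeneSpec(0, alpha0=sigma_b, alpha1=sigma_u, rho0=rho0, rho1=rho1,
                  d=d, p=p, allow_inverted=True),), ()
    )


class TestFallingFactorialAlgebra:
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(-4, 4),
           st.integers(0, 25))
    @settings(max_examples=200, deadline=None)
    def test_shifted_product_expansion(self, h, m, delta, n):
        """(n)_h (n+delta)_m expanded in falling factorials evaluates
        identically to the direct product."""
        def falling(x, k):
            out = 1
            for i in range(k):
                out *= x - i
            return out

        direct = falling(n, h) * falling(n + delta, m)
        combo = ff.prod_ff_shift(h, m, delta)
        assert sum(c * falling(n, k) for k, c in combo.items()) == pytest.approx(
            direct, rel=1e-12, abs=1e-9
        )

    def test_geometric_burst_factorial_moments(self):
        # E[(n+k)_2] for geometric k with mean B: (n)_2 + 2B (n)_1 + 2 B^2
        combo = ff.prod_ff_burst(0, 2, 3.0)
        assert combo == {2: 1.0, 1: 6.0, 0: 18.0}


class TestDerivation:
    def test_autoreg_gene_state_equation(self, autoreg_bursty):
        """The gene-state equation carries exactly +sigma_u on g_1 and
        -sigma_b on mu_{1,0}."""
        ms = derive_moment_system(autoreg_bursty, K=2)
        b = ms.basis
        row = sp.hstack([ms.A_main, ms.A_spill]).tocsr()[b.col(0, (0,))]
        entries = {c: v for c, v in zip(row.indices, row.data)}
        assert entries == {
            b.col(1, (0,)): pytest.approx(1.0),     # +sigma_u g_1
            b.col(0, (1,)): pytest.approx(-0.1),    # -sigma_b mu_{1,0}
        }

    def test_autoreg_first_moment_equations(self, autoreg_bursty):
        """mu_dot_{1,0} and mu_dot_{1,1} coefficients, term by term."""
        ms = derive_moment_system(autoreg_bursty, K=2)
        b = ms.basis
        A = sp.hstack([ms.A_main, ms.A_spill]).tocsr()
        row10 = {c: v for c, v in
                 zip(*(A[b.col(0, (1,))].indices, A[b.col(0, (1,))].data))}
        # rho_u B g0 - d mu10 + sigma_u(mu11 + g1) - sigma_b(mu20 + mu10)
        assert row10 == {
            b.col(0, (0,)): pytest.approx(5.0),      # rho_u * B
            b.col(1, (0,)): pytest.approx(1.0),      # sigma_u g1
            b.col(0, (1,)): pytest.approx(-1.1),     # -(d + sigma_b)
            b.col(1, (1,)): pytest.approx(1.0),      # sigma_u mu11
            b.col(0, (2,)): pytest.approx(-0.1),     # -sigma_b mu20
        }
        row11 = {c: v for c, v in
                 zip(*(A[b.col(1, (1,))].indices, A[b.col(1, (1,))].data))}
        assert row11 == {
            b.col(1, (0,)): pytest.approx(50.0),     # rho_b * B
            b.col(1, (1,)): pytest.approx(-2.0),     # -(d + sigma_u)
            b.col(0, (2,)): pytest.approx(0.1),      # +sigma_b mu20
        }

    def test_zero_rate_network_has_zero_rhs(self):
        net = GeneNetwork((GeneSpec(0, rho0=0, rho1=0, d=0, allow_inverted=True),), ())
        ms = derive_moment_system(net, K=2)
        assert ms.A_main.nnz == 0 and ms.A_spill.nnz == 0

    def test_equation_counts(self):
        """The Holimap moment system for autoregulation has 3 + 2h
        independent equations (cap K = h + 1); the LMA variant 1 + 2h."""
        for h in (1, 2, 3):
            net = build_autoreg(sigma_b=0.01, sigma_u=1, rho_b=20, rho_u=1,
                                d=1, h=h)
            assert derive_moment_system(net, K=h + 1).n_equations == 3 + 2 * h
            # the LMA closes at order h: same count rule with K = h
            from holimap.moments import MomentBasis

            assert MomentBasis(1, h).n_main - 1 == 1 + 2 * h

    def test_k_below_requirement_rejected(self):
        net = build_autoreg(sigma_b=0.01, sigma_u=1, rho_b=20, rho_u=1, d=1, h=2)
        with pytest.raises(MomentError, match="h \\+ 1"):
            derive_moment_system(net, K=2)

    def test_closure_status(self, autoreg_bursty):
        assert not derive_moment_system(autoreg_bursty, K=2).closed
        assert derive_moment_system(telegraph_network(), K=2).closed

    def test_probability_conservation_coefficients(self, autoreg_bursty):
        """d(sum_s g_s)/dt = 0 holds exactly at the coefficient level."""
        for net in (autoreg_bursty, telegraph_network()):
            ms = derive_moment_system(net, K=2)
            b = ms.basis
            A = sp.hstack([ms.A_main, ms.A_spill]).tocsr()
            total = sum(A[b.col(s, (0,))].toarray().ravel()
                        for s in range(b.n_states))
            assert np.abs(total).max() == 0.0


class TestOracle:
    def test_linear_telegraph_matches_cme_generator(self):
        ms = derive_moment_system(telegraph_network(), K=2)
        dev = rhs_oracle_check(ms, compile_reactions(telegraph_network()), n_max=200)
        assert dev < 1e-8

    def test_autoreg_matches_cme_generator(self, autoreg_bursty, autoreg_system):
        ms = derive_moment_system(autoreg_bursty, K=2)
        assert rhs_oracle_check(ms, autoreg_system, n_max=200) < 1e-6

    def test_zero_rate_deviation_is_zero(self):
        net = GeneNetwork((GeneSpec(0, rho0=0, rho1=0, d=0, allow_inverted=True),), ())
        ms = derive_moment_system(net, K=2)
        assert rhs_oracle_check(ms, compile_reactions(net), n_max=64) == 0.0

    def test_truncation_too_small_rejected(self):
        ms = derive_moment_system(telegraph_network(), K=2)
        with pytest.raises(MomentError, match="truncation"):
            rhs_oracle_check(ms, compile_reactions(telegraph_network()), n_max=16)


class TestIntegration:
    def test_zero_synthesis_stays_zero(self):
        ms = derive_moment_system(telegraph_network(rho1=0.0), K=2)
        states = integrate_moments(ms, ConditionalMomentState.initial(ms.basis),
                                   [0.0, 5.0])
        assert states[-1].expect({0: 1}) == pytest.approx(0.0, abs=1e-9)

    def test_telegraph_steady_mean(self):
        # mean -> B (rho0 g0 + rho1 g1) / d = 5 for symmetric switching
        ms = derive_moment_system(telegraph_network(), K=2)
        state = steady_state_moments(ms)
        assert state.g(1) == pytest.approx(0.5, abs=1e-7)
        assert state.expect({0: 1}) == pytest.approx(5.0, abs=1e-6)

    def test_constitutive_bursty_mean_and_fano(self):
        # rho = 2, B = 3 (p = 0.75), d = 1: mean 6, Fano 1 + B = 4
        net = telegraph_network(sigma_b=1.0, sigma_u=1e-9, rho0=2.0, rho1=2.0,
                                d=1.0, p=0.75)
        state = steady_state_moments(derive_moment_system(net, K=2))
        mean = state.expect({0: 1})
        mu2 = state.expect({0: 2})
        var = mu2 + mean - mean**2
        assert mean == pytest.approx(6.0, abs=1e-5)
        assert var / mean == pytest.approx(4.0, abs=1e-5)

    def test_steady_state_residual_criterion(self):
        ms = derive_moment_system(telegraph_network(), K=2)
        state = steady_state_moments(ms, tol=1e-10)
        resid = np.max(np.abs(ms.rhs(state.vec)))
        assert resid < 1e-10 * max(1.0, np.max(np.abs(state.vec)))
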