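"""FSP solvers against closed-form stationary laws and each other."""

import numpy as np
import pytest
from scipy.stats import nbinom

from holimap.analysis import hellinger
from holimap.linear_solver import (
    FSPError,
    ParamTrajectory,
    choose_truncation,
    fsp_nonlinear,
    fsp_steady,
    fsp_transient,
)
from holimap.model import build_autoreg, compile_reactions
from holimap.moments import derive_moment_system, steady_state_moments
from tests.test_moments import telegraph_network

TELEGRAPH = dict(sigma_b=1.0, sigma_u=1.0, rho0=0.0, rho1=10.0, d=1.0, p=0.0)


class TestSteady:
    def test_constitutive_bursty_is_negative_binomial(self):
        # rho = 2, p = 0.75 (B = 3), d = 1 -> NB with r = rho/d = 2
        dist = fsp_steady(dict(sigma_b=0.0, sigma_u=1.0, rho0=2.0, rho1=0.0,
                               d=1.0, p=0.75))
        ref = nbinom.pmf(np.arange(len(dist.probs)), 2.0, 0.25)
        assert np.abs(dist.probs - ref).max() < 1e-6

    def test_telegraph_mean(self):
        dist = fsp_steady(TELEGRAPH)
        # B (rho0 g0 + rho1 g1) / d with g1 = 1/2
        assert dist.mean() == pytest.approx(5.0, abs=1e-6)

    def test_equal_synthesis_rates_remove_switching_dependence(self):
        a = fsp_steady(dict(sigma_b=0.1, sigma_u=7.0, rho0=4.0, rho1=4.0,
                            d=1.0, p=0.0))
        b = fsp_steady(dict(sigma_b=9.0, sigma_u=0.2, rho0=4.0, rho1=4.0,
                            d=1.0, p=0.0))
        n = max(len(a.probs), len(b.probs))
        pa = np.pad(a.probs, (0, n - len(a.probs)))
        pb = np.pad(b.probs, (0, n - len(b.probs)))
        assert np.abs(pa - pb).max() < 1e-8

    def test_no_stationary_distribution_without_decay(self):
        with pytest.raises(FSPError, match="stationary"):
            fsp_steady(dict(sigma_b=1.0, sigma_u=1.0, rho0=1.0, rho1=1.0,
                            d=0.0, p=0.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(FSPError, match="negative"):
            fsp_steady(dict(sigma_b=-1.0, sigma_u=1.0, rho0=0.0, rho1=1.0,
                            d=1.0, p=0.0))

    def test_moments_match_moment_system(self):
        dist = fsp_steady(TELEGRAPH)
        state = steady_state_moments(derive_moment_system(telegraph_network(), K=2))
        assert dist.mean() == pytest.approx(state.expect({0: 1}), rel=1e-4)
        var_m = state.expect({0: 2}) + state.expect({0: 1}) - state.expect({0: 1}) ** 2
        assert dist.variance() == pytest.approx(var_m, rel=1e-4)


class TestTransient:
    def test_constant_rates_relax_to_steady(self):
        t_grid = np.linspace(0.0, 40.0, 9)
        dists = fsp_transient(TELEGRAPH, None, t_grid)
        steady = fsp_steady(TELEGRAPH)
        assert hellinger(dists[-1].normalized(), steady.normalized()) < 1e-4
        # truncation deficit stays bounded at every output time
        assert all(d.eps < 1e-6 for d in dists)

    def test_zero_rate_system_preserves_init(self):
        init = np.zeros((2, 8))
        init[0, 3] = 1.0
        tr = ParamTrajectory(np.array([0.0, 5.0]), np.zeros(2), np.zeros(2),
                             np.zeros(2), np.zeros(2), d=0.0)
        dists = fsp_transient(tr, init, [0.0, 2.0, 5.0])
        for d in dists:
            assert d.probs[3] == pytest.approx(1.0, abs=1e-9)

    def test_time_dependent_rates_interpolated(self):
        # switching ramps from off to on; the late-time mean must exceed
        # the frozen-initial-rate prediction and approach the final one
        t = np.linspace(0.0, 30.0, 16)
        tr = ParamTrajectory(t, sigma_b=np.linspace(0, 2, 16),
                             sigma_u=np.full(16, 1.0), rho0=np.zeros(16),
                             rho1=np.full(16, 10.0), d=1.0)
        dists = fsp_transient(tr, None, t)
        final = fsp_steady(dict(sigma_b=2.0, sigma_u=1.0, rho0=0.0, rho1=10.0,
                                d=1.0, p=0.0))
        assert dists[-1].mean() == pytest.approx(final.mean(), rel=0.05)


class TestNonlinear:
    def test_linear_input_agrees_with_fsp_steady(self):
        net = telegraph_network()
        dist = fsp_nonlinear(compile_reactions(net), network=net)
        ref = fsp_steady(TELEGRAPH)
        n = max(len(dist.probs), len(ref.probs))
        assert np.abs(np.pad(dist.probs, (0, n - len(dist.probs)))
                      - np.pad(ref.probs, (0, n - len(ref.probs)))).max() < 1e-10

    def test_slow_switching_autoreg_is_bimodal(self):
        from holimap.analysis import count_modes

        net = build_autoreg(sigma_b=0.02, sigma_u=0.1, rho_b=50.0, rho_u=1.0,
                            d=1.0, h=1, p=0.5)
        dist = fsp_nonlinear(compile_reactions(net), network=net)
        assert count_modes(dist.normalized(), 1e-3) == 2

    def test_state_space_cap(self):
        net = build_autoreg(sigma_b=0.01, sigma_u=1.0, rho_b=20.0, rho_u=1.0, d=1.0)
        with pytest.raises(FSPError, match="SSA"):
            fsp_nonlinear(compile_reactions(net), network=net,
                          caps={compile_reactions(net).protein_of_gene[0]: 10**8})


class TestTruncation:
    def test_floor(self):
        assert choose_truncation(5.0, 3.0) == 64

    def test_arithmetic(self):
        assert choose_truncation(100.0, 20.0) == 300

    def test_heavy_tail_bursty_doubles_until_contained(self):
        # B = 9 bursts: heavy geometric tails must still be contained
        dist = fsp_steady(dict(sigma_b=0.0, sigma_u=1.0, rho0=3.0, rho1=0.0,
                               d=1.0, p=0.9), tol=1e-8)
        assert dist.eps < 1e-8
        assert abs(dist.probs.sum() - 1.0) < 1e-6
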