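"""Network construction, validation, compilation and the random generator."""

import numpy as np
import pytest
from scipy import stats

from holimap.model import (
    FIXTURES,
    GeneNetwork,
    GeneSpec,
    ReactionSystem,
    RegulationEdge,
    ValidationError,
    build_autoreg,
    build_fixture,
    build_random_network,
    compile_reactions,
)


class TestValidation:
    def test_negative_rate_names_field(self):
        with pytest.raises(ValidationError, match="sigma"):
            build_autoreg(sigma_b=-0.1, sigma_u=1, rho_b=5, rho_u=1, d=1)

    def test_cooperativity_must_be_positive(self):
        with pytest.raises(ValidationError, match="h"):
            build_autoreg(sigma_b=0.1, sigma_u=1, rho_b=5, rho_u=1, d=1, h=0)

    def test_burst_parameter_range(self):
        with pytest.raises(ValidationError, match="p"):
            build_autoreg(sigma_b=0.1, sigma_u=1, rho_b=5, rho_u=1, d=1, p=1.0)

    def test_inverted_synthesis_needs_flag(self):
        with pytest.raises(ValidationError, match="rho1"):
            GeneSpec(0, rho0=5.0, rho1=1.0, d=1.0)
        GeneSpec(0, rho0=5.0, rho1=1.0, d=1.0, allow_inverted=True)

    def test_edge_indices_checked(self):
        g = GeneSpec(0, rho0=0.0, rho1=1.0, d=1.0)
        with pytest.raises(ValidationError, match="out of range"):
            GeneNetwork((g,), (RegulationEdge(0, 3, "activating", 0.1),))

    def test_sigma_u_only_on_reversible_edges(self):
        with pytest.raises(ValidationError, match="reversible"):
            RegulationEdge(0, 0, "activating", 0.1, sigma_u=1.0, reversible=False)


class TestAutoreg:
    def test_burst_size_from_p(self):
        net = build_autoreg(sigma_b=0.1, sigma_u=1, rho_b=50, rho_u=1, d=1, p=0.5)
        assert net.genes[0].burst_size == pytest.approx(1.0)

    def test_burst_size_via_mean(self):
        net = build_autoreg(sigma_b=0.1, sigma_u=1, rho_b=50, rho_u=1, d=1, B=3.0)
        assert net.genes[0].p == pytest.approx(0.75)

    def test_p_zero_is_single_molecule_synthesis(self):
        net = build_autoreg(sigma_b=0.1, sigma_u=1, rho_b=50, rho_u=1, d=1, p=0.0)
        system = compile_reactions(net)
        syn = [r for r in system.reactions if r.name.startswith("P1_syn")]
        assert len(syn) == 2
        for r in syn:
            assert r.burst_species == -1  # fixed +1 jump, not a geometric draw
            assert dict(r.stoich)[system.protein_of_gene[0]] == 1

    def test_no_feedback_has_no_bimolecular_channel(self):
        net = build_autoreg(sigma_b=0.0, sigma_u=1, rho_b=50, rho_u=1, d=1)
        system = compile_reactions(net)
        prot = system.protein_of_gene[0]
        for r in system.reactions:
            if r.rate == 0:
                continue
            orders = dict(r.orders)
            # no active channel combines a gene factor with a protein factor
            assert not (orders.get(prot, 0) > 0 and len(orders) > 1)

    def test_channel_enumeration(self):
        # bind, unbind, two synthesis channels, one decay channel
        net = build_autoreg(sigma_b=0.1, sigma_u=1, rho_b=50, rho_u=1, d=1, p=0.5)
        assert len(compile_reactions(net).reactions) == 5


class TestRandomNetwork:
    def test_determinism(self):
        a = build_random_network(10, seed=42)
        b = build_random_network(10, seed=42)
        assert a.edges == b.edges

    def test_reference_rates(self):
        net = build_random_network(6, seed=0)
        g = net.genes[0]
        assert (g.alpha0, g.alpha1, g.rho0, g.rho1, g.d) == (0.5, 0.5, 5.4, 81.0, 1.0)
        for e in net.edges:
            assert e.sigma == 0.01 and e.h == 1 and not e.reversible

    def test_edge_count_distribution(self):
        # total edges ~ Binomial(M^2, 2/M); chi-squared over many seeds
        M, n_seeds = 5, 4000
        counts = np.array([len(build_random_network(M, s).edges)
                           for s in range(n_seeds)])
        assert counts.mean() == pytest.approx(2 * M, rel=0.05)
        k = np.arange(M * M + 1)
        pmf = stats.binom.pmf(k, M * M, 2.0 / M)
        # pool tail bins with small expectation
        obs = np.bincount(counts, minlength=M * M + 1).astype(float)
        mask = pmf * n_seeds >= 5
        obs_p = np.append(obs[mask], obs[~mask].sum())
        exp_p = np.append(pmf[mask], pmf[~mask].sum()) * n_seeds
        _chi, p = stats.chisquare(obs_p, exp_p * obs_p.sum() / exp_p.sum())
        assert p > 1e-3

    def test_m_below_one_rejected(self):
        with pytest.raises(ValidationError):
            build_random_network(0, seed=1)

    def test_self_edges_allowed(self):
        edges = [e for s in range(200) for e in build_random_network(3, s).edges]
        assert any(e.regulator == e.target for e in edges)


class TestFixtures:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValidationError, match="repressilator"):
            build_fixture("nonsense")

    def test_repressilator_default_cooperativity(self):
        net = build_fixture("repressilator")
        assert all(e.h == 3 for e in net.edges)
        assert all(not g.bursty for g in net.genes)

    def test_repressilator_h1_valid(self):
        net = build_fixture("repressilator", h1=1, h2=1, h3=1)
        assert all(e.h == 1 for e in net.edges)

    def test_toggle_is_mutual_repression(self):
        net = build_fixture("toggle", h1=2, h2=2)
        assert {(e.regulator, e.target) for e in net.edges} == {(0, 1), (1, 0)}
        assert all(e.sign == "repressing" and e.h == 2 for e in net.edges)

    def test_mirna_fixture_species(self):
        system = build_fixture("mirna_mrna")
        assert isinstance(system, ReactionSystem)
        assert {"C1", "C2", "M", "R"} <= set(system.species)
        names = {r.name for r in system.reactions}
        assert {"C1_mrna_decay", "C1_mirna_decay", "C2_mrna_decay",
                "C2_mirna_decay"} <= names

    @pytest.mark.parametrize("name", FIXTURES)
    def test_all_fixtures_have_nonneg_propensities(self, name, rng):
        obj = build_fixture(name)
        system = obj if isinstance(obj, ReactionSystem) else compile_reactions(obj)
        counts = rng.integers(0, 30, size=(10_000, system.n_species))
        # gene indicators must be consistent 0/1 pairs
        for off, on in system.gene_state_pairs:
            bit = rng.integers(0, 2, size=len(counts))
            counts[:, on] = bit
            counts[:, off] = 1 - bit
        assert (system.propensities(counts) >= 0).all()
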