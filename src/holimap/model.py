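"""Gene regulatory network models and their reaction-system representation.

A :class:`GeneNetwork` is a set of two-state genes (unbound/inactive state 0,
bound/active state 1) coupled by protein-gene regulation edges.  Protein
synthesis may be bursty, with burst sizes drawn from a geometric
distribution ``P(k = n) = p^n (1 - p)`` whose mean is ``B = p / (1 - p)``.
Regulation is mediated by cooperative binding of ``h`` copies of the
regulator protein to the target gene promoter, with the combinatorial
(falling-factorial) propensity ``sigma * n (n-1) ... (n-h+1)``.

Two regulation conventions are supported:

* reversible motif binding ``G + h P <=> G*`` (binding sequesters the
  ``h`` proteins, unbinding releases them) — used by the single-gene
  autoregulatory loop and the two-/three-node motifs;
* irreversible regulation events ``G + h P_i -> G*`` / ``G* + h P_i -> G``
  that consume the regulator — the convention of the general stochastic
  network model used for randomly connected networks.

:func:`compile_reactions` lowers a network to a :class:`ReactionSystem`, a
flat list of reaction channels with combinatorial propensities, consumed by
the SSA, the CME/FSP solvers and the moment-equation deriver.  Gene states
are encoded as paired 0/1 indicator species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ACTIVATING = "activating"
REPRESSING = "repressing"

FIXTURES = (
    "two_node",
    "toggle",
    "repressilator",
    "goodwin",
    "sequestration",
    "phosphorylation",
    "mrna_degradation_control",
    "mirna_mrna",
)


class ValidationError(ValueError):
    """A model field violates its invariants."""


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")


def burst_parameter_from_mean(B: float) -> float:
    """Invert the mean burst size B = p / (1 - p) to the geometric parameter p."""
    if B < 0:
        raise ValidationError(f"mean burst size must be non-negative, got {B}")
    return B / (1.0 + B)


@dataclass(frozen=True)
class GeneSpec:
    """One two-state gene.

    ``alpha0``/``alpha1`` are the spontaneous activation (0 -> 1) and
    inactivation (1 -> 0) rates, ``rho0``/``rho1`` the synthesis (burst)
    frequencies in the two states, ``d`` the protein degradation rate and
    ``p`` the geometric burst parameter (``p = 0`` means each synthesis
    event produces exactly one molecule).  By convention state 1 is the
    transcriptionally active state (``rho1 > rho0``); motif models where
    the bound state is the repressed one set ``allow_inverted``.
    """

    index: int
    alpha0: float = 0.0
    alpha1: float = 0.0
    rho0: float = 0.0
    rho1: float = 0.0
    d: float = 1.0
    p: float = 0.0
    allow_inverted: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "rho0", "rho1", "d"):
            _check_nonneg(name, getattr(self, name))
        if not 0.0 <= self.p < 1.0:
            raise ValidationError(f"burst parameter p must lie in [0, 1), got {self.p}")
        if self.rho1 <= self.rho0 and not self.allow_inverted:
            raise ValidationError(
                f"gene {self.index}: rho1 <= rho0 (active state is not the "
                "high-synthesis state); pass allow_inverted=True if intended"
            )

    @property
    def burst_size(self) -> float:
        """Mean burst size B = p / (1 - p); 1 for non-bursty synthesis."""
        return self.p / (1.0 - self.p) if self.p > 0 else 1.0

    @property
    def bursty(self) -> bool:
        return self.p > 0


@dataclass(frozen=True)
class RegulationEdge:
    """Regulation of gene ``target`` by ``h`` copies of protein ``regulator``.

    ``sigma`` is the protein-dependent switching rate (per time per
    count^h).  For irreversible edges the sign decides the direction of
    the driven switch: activating edges drive 0 -> 1 and repressing edges
    1 -> 0, consuming the ``h`` regulator proteins.  Reversible motif
    edges always bind 0 -> 1 (sequestering ``h`` proteins) and unbind
    1 -> 0 at rate ``sigma_u`` (releasing them); their sign is purely
    informational (set from the synthesis-rate ordering of the target).
    """

    regulator: int
    target: int
    sign: str
    sigma: float
    h: int = 1
    reversible: bool = False
    sigma_u: float = 0.0

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValidationError(f"cooperativity h must be >= 1, got {self.h}")
        _check_nonneg("sigma", self.sigma)
        _check_nonneg("sigma_u", self.sigma_u)
        if self.sign not in (ACTIVATING, REPRESSING):
            raise ValidationError(f"sign must be {ACTIVATING!r} or {REPRESSING!r}")
        if self.sigma_u > 0 and not self.reversible:
            raise ValidationError("sigma_u is only meaningful for reversible edges")


@dataclass(frozen=True)
class GeneNetwork:
    genes: tuple[GeneSpec, ...]
    edges: tuple[RegulationEdge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "edges", tuple(self.edges))
        for j, g in enumerate(self.genes):
            if g.index != j:
                raise ValidationError(f"gene at position {j} has index {g.index}")
        for e in self.edges:
            for attr in ("regulator", "target"):
                idx = getattr(e, attr)
                if not 0 <= idx < self.n_genes:
                    raise ValidationError(f"edge {attr} {idx} out of range")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def max_cooperativity(self) -> int:
        return max((e.h for e in self.edges), default=1)

    def regulators_of(self, j: int) -> list[RegulationEdge]:
        return [e for e in self.edges if e.target == j]


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    Propensity = ``rate * prod_i ff(n_i, orders[i])`` with
    ``ff(n, h) = n (n-1) ... (n-h+1)``, optionally multiplied by a
    Michaelis-Menten factor ``n_s / (K + n_s)`` (``mm = (s, K)``, with
    ``rate`` playing the role of V).  Firing applies ``stoich`` and, for
    burst channels, additionally adds a geometric(``burst_p``) number of
    copies of ``burst_species``.
    """

    name: str
    rate: float
    orders: tuple[tuple[int, int], ...] = ()
    stoich: tuple[tuple[int, int], ...] = ()
    burst_species: int = -1
    burst_p: float = 0.0
    mm: tuple[int, float] | None = None
    gene_flip: tuple[int, int, int] | None = None  # (gene, from_state, to_state)

    def propensity(self, counts: np.ndarray) -> np.ndarray:
        """Evaluate the propensity on one count vector or a batch (..., S)."""
        a = np.full(np.asarray(counts).shape[:-1], self.rate, dtype=float)
        c = np.asarray(counts, dtype=float)
        for s, h in self.orders:
            for i in range(h):
                a = a * (c[..., s] - i)
        if self.mm is not None:
            s, K = self.mm
            a = a * c[..., s] / (K + c[..., s])
        return a


@dataclass
class ReactionSystem:
    """Flat reaction-channel representation of a stochastic model."""

    species: list[str]
    reactions: list[Reaction]
    # indicator-species pairs (off_idx, on_idx), one per gene
    gene_state_pairs: list[tuple[int, int]] = field(default_factory=list)
    # protein (or tracked-output) species index per gene
    protein_of_gene: list[int] = field(default_factory=list)
    # non-default initial copy numbers, e.g. a fixed enzyme pool
    extra_initial: dict[int, int] = field(default_factory=dict)
    name: str = ""

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}; have {self.species}") from None

    def initial_counts(self) -> np.ndarray:
        """Default initial condition: all genes unbound, no molecules."""
        x = np.zeros(self.n_species, dtype=np.int64)
        for off, _on in self.gene_state_pairs:
            x[off] = 1
        for s, n in self.extra_initial.items():
            x[s] = n
        return x

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        return np.stack([r.propensity(counts) for r in self.reactions], axis=-1)


# ---------------------------------------------------------------------------
# constructors


def build_autoreg(
    sigma_b: float,
    sigma_u: float,
    rho_b: float,
    rho_u: float,
    d: float,
    h: int = 1,
    p: float = 0.0,
    B: float | None = None,
) -> GeneNetwork:
    """Autoregulatory feedback loop with reversible cooperative binding.

    ``G + h P <=> G*`` at rates (sigma_b, sigma_u), bursty synthesis at
    burst frequencies rho_u (unbound) / rho_b (bound), decay ``d``.  The
    loop is a positive feedback when ``rho_b > rho_u`` and negative
    otherwise.  Pass either the geometric parameter ``p`` or the mean
    burst size ``B``.
    """
    if B is not None:
        p = burst_parameter_from_mean(B)
    gene = GeneSpec(
        0, alpha0=0.0, alpha1=0.0, rho0=rho_u, rho1=rho_b, d=d, p=p, allow_inverted=True
    )
    sign = ACTIVATING if rho_b > rho_u else REPRESSING
    edge = RegulationEdge(0, 0, sign, sigma_b, h=h, reversible=True, sigma_u=sigma_u)
    return GeneNetwork((gene,), (edge,))


def build_random_network(M: int, seed: int) -> GeneNetwork:
    """Randomly connected M-gene network.

    Every ordered gene pair (self-pairs included) is independently
    connected with probability 2/M, so the network carries 2M directed
    edges on average; each edge is activating or repressing with equal
    probability.  Rates follow the reference parameter set
    ``d = 1, h = 1, rho1 = 81, rho0 = 5.4, alpha0 = alpha1 = 0.5,
    sigma = 0.01``; regulation events consume the regulator protein
    (irreversible convention).  Pure function of ``(M, seed)``.
    """
    if M < 1:
        raise ValidationError(f"network size M must be >= 1, got {M}")
    rng = np.random.default_rng(seed)
    genes = tuple(
        GeneSpec(j, alpha0=0.5, alpha1=0.5, rho0=5.4, rho1=81.0, d=1.0) for j in range(M)
    )
    edges = []
    for i in range(M):  # regulator
        for j in range(M):  # target
            if rng.random() < 2.0 / M:
                sign = ACTIVATING if rng.random() < 0.5 else REPRESSING
                edges.append(RegulationEdge(i, j, sign, 0.01, h=1))
    return GeneNetwork(genes, tuple(edges))


def _motif_gene(j: int, rho_u: float, rho_b: float, d: float) -> GeneSpec:
    return GeneSpec(j, rho0=rho_u, rho1=rho_b, d=d, allow_inverted=True)


def _cycle_network(
    n: int, rho_u: float, rho_b: float, d: float, sigma_b: float, sigma_u: float, hs
) -> GeneNetwork:
    genes = tuple(_motif_gene(j, rho_u, rho_b, d) for j in range(n))
    sign = ACTIVATING if rho_b > rho_u else REPRESSING
    edges = tuple(
        RegulationEdge(
            j, (j + 1) % n, sign, sigma_b, h=hs[j], reversible=True, sigma_u=sigma_u
        )
        for j in range(n)
    )
    return GeneNetwork(genes, edges)


def build_fixture(name: str, **overrides):
    """Named in-text network motifs.

    Transcriptional motifs (``two_node``, ``toggle``, ``repressilator``,
    ``goodwin``) return a :class:`GeneNetwork` with non-bursty synthesis
    and reversible binding; post-translational / post-transcriptional
    motifs (``sequestration``, ``phosphorylation``,
    ``mrna_degradation_control``, ``mirna_mrna``) return a
    :class:`ReactionSystem` directly.  Rate values for the latter group
    are documented placeholder defaults chosen to give molecule numbers
    of order tens; override any keyword to change them.
    """
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; valid fixtures: {FIXTURES}")
    return _FIXTURE_BUILDERS[name](**overrides)


def _fixture_two_node(
    sigma_b1: float = 300.0,
    sigma_b2: float = 3e-3,
    sigma_u1: float = 100.0,
    sigma_u2: float = 100.0,
    rho_u1: float = 40.0,
    rho_b1: float = 1.0,
    rho_u2: float = 0.2,
    rho_b2: float = 40.0,
    d1: float = 1.0,
    d2: float = 1.0,
    h1: int = 1,
    h2: int = 1,
) -> GeneNetwork:
    """Two-node negative feedback loop: P1 activates G2, P2 represses G1.

    Binding rates are indexed by the *target* gene: ``sigma_b1`` is the
    rate at which h2 copies of P2 bind G1, ``sigma_b2`` the rate at which
    h1 copies of P1 bind G2 (likewise for the unbinding rates).  Both
    genes switch fast (sigma_u >> d); the defaults sit in the regime
    where the low-copy repressor P2 rebinds G1 essentially instantly
    whenever present, so the protein P1 distribution is bimodal even
    though neither slow switching nor cooperativity is present
    (type-III bimodality).
    """
    g1 = _motif_gene(0, rho_u1, rho_b1, d1)
    g2 = _motif_gene(1, rho_u2, rho_b2, d2)
    e_to_g2 = RegulationEdge(0, 1, ACTIVATING, sigma_b2, h=h1, reversible=True, sigma_u=sigma_u2)
    e_to_g1 = RegulationEdge(1, 0, REPRESSING, sigma_b1, h=h2, reversible=True, sigma_u=sigma_u1)
    return GeneNetwork((g1, g2), (e_to_g2, e_to_g1))


def _fixture_toggle(
    sigma_b1: float = 0.3,
    sigma_b2: float = 0.3,
    sigma_u1: float = 50.0,
    sigma_u2: float = 50.0,
    rho_u: float = 40.0,
    rho_b: float = 1.0,
    d: float = 1.0,
    h1: int = 2,
    h2: int = 2,
) -> GeneNetwork:
    """Toggle switch: two genes mutually repressing with cooperativity 2.

    Binding rates are indexed by the target gene (``sigma_b1`` = rate of
    h2 copies of P2 binding G1).  The defaults are deterministically
    bistable (two stable fixed points of the rate equations) and both
    genes switch fast relative to decay.
    """
    genes = (_motif_gene(0, rho_u, rho_b, d), _motif_gene(1, rho_u, rho_b, d))
    e_to_g2 = RegulationEdge(0, 1, REPRESSING, sigma_b2, h=h1, reversible=True, sigma_u=sigma_u2)
    e_to_g1 = RegulationEdge(1, 0, REPRESSING, sigma_b1, h=h2, reversible=True, sigma_u=sigma_u1)
    return GeneNetwork(genes, (e_to_g2, e_to_g1))


def _fixture_repressilator(
    sigma_b: float = 8e-6,
    sigma_u: float = 1.0,
    rho_u: float = 150.0,
    rho_b: float = 0.0,
    d: float = 1.0,
    h1: int = 3,
    h2: int = 3,
    h3: int = 3,
) -> GeneNetwork:
    """Three-gene repression cycle; cooperativity 3 by default so the
    deterministic rate equations sustain oscillations (no oscillation for
    h <= 2).  The repression threshold (sigma_u / sigma_b)^(1/3) = 50
    molecules sits well below the unrepressed mean of 150."""
    return _cycle_network(3, rho_u, rho_b, d, sigma_b, sigma_u, (h1, h2, h3))


def _fixture_goodwin(
    sigma_b: float = 6.4e-4,
    sigma_u: float = 10.0,
    rho_u: float = 50.0,
    rho_b: float = 0.5,
    d: float = 1.0,
    h1: int = 3,
    h2: int = 3,
    h3: int = 3,
) -> GeneNetwork:
    """Goodwin-type cycle: one repression, two activations."""
    genes = tuple(
        _motif_gene(j, rho_u if j == 0 else 0.5, rho_b if j == 0 else 50.0, d)
        for j in range(3)
    )
    hs = (h1, h2, h3)
    edges = []
    for j in range(3):
        target = (j + 1) % 3
        sign = REPRESSING if target == 0 else ACTIVATING
        edges.append(
            RegulationEdge(j, target, sign, sigma_b, h=hs[j], reversible=True, sigma_u=sigma_u)
        )
    return GeneNetwork(genes, tuple(edges))


def _post_reg_base(n_genes, extra_species):
    """Species table with gene indicator pairs followed by extra species."""
    species = []
    pairs = []
    for j in range(n_genes):
        species += [f"G{j + 1}", f"G{j + 1}*"]
        pairs.append((2 * j, 2 * j + 1))
    base = len(species)
    species += list(extra_species)
    return species, pairs, base


def _gene_channels(j, off, on, prot, g: GeneSpec, reactions):
    if g.alpha0 > 0:
        reactions.append(
            Reaction(f"G{j+1}_on", g.alpha0, ((off, 1),), ((off, -1), (on, 1)),
                     gene_flip=(j, 0, 1))
        )
    if g.alpha1 > 0:
        reactions.append(
            Reaction(f"G{j+1}_off", g.alpha1, ((on, 1),), ((off, 1), (on, -1)),
                     gene_flip=(j, 1, 0))
        )
    for state, idx, rho in ((0, off, g.rho0), (1, on, g.rho1)):
        if rho > 0:
            if g.bursty:
                reactions.append(
                    Reaction(f"P{j+1}_burst_s{state}", rho, ((idx, 1),), (),
                             burst_species=prot, burst_p=g.p)
                )
            else:
                reactions.append(
                    Reaction(f"P{j+1}_syn_s{state}", rho, ((idx, 1),), ((prot, 1),))
                )
    if g.d > 0:
        reactions.append(Reaction(f"P{j+1}_decay", g.d, ((prot, 1),), ((prot, -1),)))


def compile_reactions(network: GeneNetwork) -> ReactionSystem:
    """Lower a gene network to its reaction channels.

    Species ordering: for each gene j the indicator pair (Gj, Gj*) at
    positions (2j, 2j+1), followed by the proteins P1..PM.  Channels per
    gene: spontaneous switching (if rates nonzero), one synthesis channel
    per gene state with nonzero rate, one decay channel; plus one binding
    channel per edge (and an unbinding channel for reversible edges).
    """
    M = network.n_genes
    species = []
    for j in range(M):
        species += [f"G{j + 1}", f"G{j + 1}*"]
    prot0 = 2 * M
    species += [f"P{j + 1}" for j in range(M)]
    reactions: list[Reaction] = []
    for j, g in enumerate(network.genes):
        _gene_channels(j, 2 * j, 2 * j + 1, prot0 + j, g, reactions)
    for e in network.edges:
        off, on = 2 * e.target, 2 * e.target + 1
        pr = prot0 + e.regulator
        if e.reversible:
            reactions.append(
                Reaction(
                    f"bind_P{e.regulator+1}_G{e.target+1}", e.sigma,
                    ((off, 1), (pr, e.h)), ((off, -1), (on, 1), (pr, -e.h)),
                    gene_flip=(e.target, 0, 1),
                )
            )
            reactions.append(
                Reaction(
                    f"unbind_P{e.regulator+1}_G{e.target+1}", e.sigma_u,
                    ((on, 1),), ((off, 1), (on, -1), (pr, e.h)),
                    gene_flip=(e.target, 1, 0),
                )
            )
        elif e.sign == ACTIVATING:
            reactions.append(
                Reaction(
                    f"act_P{e.regulator+1}_G{e.target+1}", e.sigma,
                    ((off, 1), (pr, e.h)), ((off, -1), (on, 1), (pr, -e.h)),
                    gene_flip=(e.target, 0, 1),
                )
            )
        else:
            reactions.append(
                Reaction(
                    f"rep_P{e.regulator+1}_G{e.target+1}", e.sigma,
                    ((on, 1), (pr, e.h)), ((off, 1), (on, -1), (pr, -e.h)),
                    gene_flip=(e.target, 1, 0),
                )
            )
    return ReactionSystem(
        species=species,
        reactions=reactions,
        gene_state_pairs=[(2 * j, 2 * j + 1) for j in range(M)],
        protein_of_gene=[prot0 + j for j in range(M)],
        name="gene_network",
    )


# ---------------------------------------------------------------------------
# post-translational / post-transcriptional fixtures (ReactionSystem directly)


def _fixture_sequestration(
    sigma_b: float = 0.01,
    sigma_u: float = 2.0,
    rho_u1: float = 40.0,
    rho_b1: float = 4.0,
    rho_u2: float = 20.0,
    rho_b2: float = 2.0,
    d1: float = 1.0,
    d2: float = 1.0,
    k_bind: float = 0.02,
) -> ReactionSystem:
    """Two autoregulated genes whose proteins sequester each other.

    P1 + P2 -> C forms an inactive complex at rate ``k_bind``; each
    protein also negatively autoregulates its own gene (h = 1).
    """
    species, pairs, base = _post_reg_base(2,["P1", "P2", "C"])
    p1, p2 = base, base + 1
    reactions: list[Reaction] = []
    for j, (rho_u, rho_b, d) in enumerate(((rho_u1, rho_b1, d1), (rho_u2, rho_b2, d2))):
        off, on = pairs[j]
        g = _motif_gene(j, rho_u, rho_b, d)
        _gene_channels(j, off, on, base + j, g, reactions)
        reactions.append(
            Reaction(
                f"bind_P{j+1}_G{j+1}", sigma_b, ((off, 1), (base + j, 1)),
                ((off, -1), (on, 1), (base + j, -1)), gene_flip=(j, 0, 1),
            )
        )
        reactions.append(
            Reaction(
                f"unbind_P{j+1}_G{j+1}", sigma_u, ((on, 1),),
                ((off, 1), (on, -1), (base + j, 1)), gene_flip=(j, 1, 0),
            )
        )
    reactions.append(
        Reaction("sequester", k_bind, ((p1, 1), (p2, 1)), ((p1, -1), (p2, -1), (base + 2, 1)))
    )
    return ReactionSystem(species, reactions, pairs, [p1, p2], name="sequestration")


def _fixture_phosphorylation(
    sigma_b: float = 0.01,
    sigma_u: float = 2.0,
    rho_u: float = 50.0,
    rho_b: float = 5.0,
    d: float = 1.0,
    V1: float = 30.0,
    K1: float = 20.0,
    V2: float = 30.0,
    K2: float = 20.0,
    V3: float = 20.0,
    K3: float = 20.0,
    V4: float = 20.0,
    K4: float = 20.0,
) -> ReactionSystem:
    """Autoregulation with two-step reversible phosphorylation P -> P1 -> P2.

    Phosphorylation/dephosphorylation are Michaelis-Menten channels
    (V_i, K_i); the doubly phosphorylated form P2 binds the gene and
    represses it (bound state is low-synthesis).
    """
    species, pairs, base = _post_reg_base(1,["P", "P1", "P2"])
    P, P1, P2 = base, base + 1, base + 2
    off, on = pairs[0]
    reactions: list[Reaction] = []
    g = _motif_gene(0, rho_u, rho_b, d)
    _gene_channels(0, off, on, P, g, reactions)
    reactions += [
        Reaction("phos1", V1, (), ((P, -1), (P1, 1)), mm=(P, K1)),
        Reaction("dephos1", V2, (), ((P1, -1), (P, 1)), mm=(P1, K2)),
        Reaction("phos2", V3, (), ((P1, -1), (P2, 1)), mm=(P1, K3)),
        Reaction("dephos2", V4, (), ((P2, -1), (P1, 1)), mm=(P2, K4)),
        Reaction("bind_P2_G", sigma_b, ((off, 1), (P2, 1)),
                 ((off, -1), (on, 1), (P2, -1)), gene_flip=(0, 0, 1)),
        Reaction("unbind_P2_G", sigma_u, ((on, 1),),
                 ((off, 1), (on, -1), (P2, 1)), gene_flip=(0, 1, 0)),
    ]
    return ReactionSystem(species, reactions, pairs, [P], name="phosphorylation")


def _fixture_mrna_degradation_control(
    sigma_b: float = 0.01,
    sigma_u: float = 2.0,
    rho_u: float = 60.0,
    rho_b: float = 6.0,
    d: float = 0.5,
    alpha: float = 0.1,
    k_act: float = 1.0,
    k_deact: float = 1.0,
    n_enzyme: int = 10,
) -> ReactionSystem:
    """Autoregulated gene whose mRNA is also degraded enzymatically.

    The enzyme interconverts between inactive E and active E*; the
    channel M + E* -> E* removes mRNA at rate ``alpha`` per (M, E*) pair
    on top of the spontaneous decay ``d``.  The autoregulation is
    negative (mRNA binds its own gene).  ``n_enzyme`` enzyme molecules
    are placed in the inactive form initially.
    """
    species, pairs, base = _post_reg_base(1,["M", "E", "E*"])
    Mi, E, Es = base, base + 1, base + 2
    off, on = pairs[0]
    reactions: list[Reaction] = []
    g = _motif_gene(0, rho_u, rho_b, d)
    _gene_channels(0, off, on, Mi, g, reactions)
    reactions += [
        Reaction("bind_M_G", sigma_b, ((off, 1), (Mi, 1)),
                 ((off, -1), (on, 1), (Mi, -1)), gene_flip=(0, 0, 1)),
        Reaction("unbind_M_G", sigma_u, ((on, 1),),
                 ((off, 1), (on, -1), (Mi, 1)), gene_flip=(0, 1, 0)),
        Reaction("E_act", k_act, ((E, 1),), ((E, -1), (Es, 1))),
        Reaction("E_deact", k_deact, ((Es, 1),), ((Es, -1), (E, 1))),
        Reaction("enzymatic_decay", alpha, ((Mi, 1), (Es, 1)), ((Mi, -1),)),
    ]
    return ReactionSystem(
        species, reactions, pairs, [Mi],
        extra_initial={E: n_enzyme}, name="mrna_degradation_control",
    )


def _fixture_mirna_mrna(
    rho1: float = 40.0,
    rho2: float = 20.0,
    d1: float = 1.0,
    d2: float = 1.0,
    alpha: float = 0.02,
    beta: float = 1.0,
    a1: float = 2.0,
    a2: float = 0.5,
    b1: float = 4.0,
    b2: float = 1.0,
    alpha_g: float = 0.5,
    beta_g: float = 0.5,
) -> ReactionSystem:
    """mRNA with two microRNA binding sites.

    Gene G1 transcribes the mRNA M, gene G2 the microRNA R (both genes
    switch spontaneously at rates ``alpha_g``/``beta_g`` and transcribe
    only in the active state).  M + R <=> C1 (rates alpha, beta) occupies
    the first site and C1 + R <=> C2 the second.  Inside a complex the
    mRNA is degraded at a1 (C1) / b1 (C2), releasing the bound microRNA,
    and one microRNA is degraded at a2 (C1 -> M) / b2 (C2 -> C1).
    """
    species, pairs, base = _post_reg_base(2,["M", "R", "C1", "C2"])
    Mi, R, C1, C2 = base, base + 1, base + 2, base + 3
    reactions: list[Reaction] = []
    for j, (rho, prod) in enumerate(((rho1, Mi), (rho2, R))):
        off, on = pairs[j]
        reactions += [
            Reaction(f"G{j+1}_on", alpha_g, ((off, 1),), ((off, -1), (on, 1)),
                     gene_flip=(j, 0, 1)),
            Reaction(f"G{j+1}_off", beta_g, ((on, 1),), ((off, 1), (on, -1)),
                     gene_flip=(j, 1, 0)),
            Reaction(f"syn_{j+1}", rho, ((on, 1),), ((prod, 1),)),
        ]
    reactions += [
        Reaction("M_decay", d1, ((Mi, 1),), ((Mi, -1),)),
        Reaction("R_decay", d2, ((R, 1),), ((R, -1),)),
        Reaction("bind1", alpha, ((Mi, 1), (R, 1)), ((Mi, -1), (R, -1), (C1, 1))),
        Reaction("unbind1", beta, ((C1, 1),), ((C1, -1), (Mi, 1), (R, 1))),
        Reaction("bind2", alpha, ((C1, 1), (R, 1)), ((C1, -1), (R, -1), (C2, 1))),
        Reaction("unbind2", beta, ((C2, 1),), ((C2, -1), (C1, 1), (R, 1))),
        Reaction("C1_mrna_decay", a1, ((C1, 1),), ((C1, -1), (R, 1))),
        Reaction("C1_mirna_decay", a2, ((C1, 1),), ((C1, -1), (Mi, 1))),
        Reaction("C2_mrna_decay", b1, ((C2, 1),), ((C2, -1), (R, 2))),
        Reaction("C2_mirna_decay", b2, ((C2, 1),), ((C2, -1), (C1, 1))),
    ]
    return ReactionSystem(species, reactions, pairs, [Mi], name="mirna_mrna")


_FIXTURE_BUILDERS = {
    "two_node": _fixture_two_node,
    "toggle": _fixture_toggle,
    "repressilator": _fixture_repressilator,
    "goodwin": _fixture_goodwin,
    "sequestration": _fixture_sequestration,
    "phosphorylation": _fixture_phosphorylation,
    "mrna_degradation_control": _fixture_mrna_degradation_control,
    "mirna_mrna": _fixture_mirna_mrna,
}


def with_rates(network: GeneNetwork, **gene0_overrides) -> GeneNetwork:
    """Convenience: replace fields of a single-gene network's gene 0."""
    if network.n_genes != 1:
        raise ValidationError("with_rates only supports single-gene networks")
    return GeneNetwork((replace(network.genes[0], **gene0_overrides),), network.edges)
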