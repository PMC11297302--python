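"""Conditional factorial-moment equations of gene regulatory networks.

For a network of M two-state genes, the moment state tracks, for every
joint gene-state vector s in {0,1}^M, the probability ``g_s`` and the
conditional factorial moments

    mu_{m, s} = E[ prod_j (n_j)_{m_j} ; G = s ],

with ``(n)_m = n (n-1) ... (n-m+1)`` and the multi-order ``m`` capped at
``|m| <= K``.  The time-evolution equations are derived directly from the
chemical master equation: for each reaction channel with propensity
``a(x)`` and jump ``x -> x'``, the contribution to ``d E[f]/dt`` is
``E[a(x) (f(x') - f(x))]``, which for combinatorial (falling-factorial)
propensities expands exactly into a linear combination of factorial
moments.  The resulting system is linear in the moments; it is closed for
linear networks and references moments of order ``|m| + h`` for binding
reactions of cooperativity ``h`` (the closure problem the mapping module
resolves).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from . import _ffpoly as ff
from ._cme import build_generator
from .model import GeneNetwork, Reaction, ReactionSystem, compile_reactions


class MomentError(RuntimeError):
    pass


def multiindices(n: int, kmax: int) -> list[tuple[int, ...]]:
    """All multi-orders over n species with total order <= kmax, sorted by
    (total order, lexicographic)."""
    out = []
    for total in range(kmax + 1):
        out.extend(
            sorted(
                m
                for m in itertools.product(range(total + 1), repeat=n)
                if sum(m) == total
            )
        )
    return out


class MomentBasis:
    """Index space of conditional factorial moments (joint state, multi-order)."""

    def __init__(self, n_genes: int, K: int, K_ext: int | None = None):
        if n_genes > 12:
            raise MomentError(
                "joint conditional moments scale exponentially in the number "
                f"of genes; refusing M = {n_genes} > 12 (use the hybrid "
                "SSA+Holimap method for large networks)"
            )
        self.n_genes = n_genes
        self.K = K
        self.K_ext = K if K_ext is None else K_ext
        self.n_states = 2**n_genes
        self.orders = multiindices(n_genes, self.K_ext)
        self.n_orders_main = sum(1 for m in self.orders if sum(m) <= K)
        self._order_index = {m: i for i, m in enumerate(self.orders)}
        self.n_main = self.n_states * self.n_orders_main
        self.n_ext = self.n_states * len(self.orders)

    def col(self, s: int, m: tuple[int, ...]) -> int:
        return self._order_index[m] * self.n_states + s

    def is_main(self, col: int) -> bool:
        return col < self.n_main

    def entries(self, main_only: bool = True):
        n_ord = self.n_orders_main if main_only else len(self.orders)
        for i in range(n_ord):
            for s in range(self.n_states):
                yield s, self.orders[i]

    def states_matching(self, cond) -> list[int]:
        """Joint states consistent with a partial assignment {gene: state}."""
        out = []
        for s in range(self.n_states):
            if all((s >> j) & 1 == v for j, v in cond):
                out.append(s)
        return out


@dataclass
class _RxView:
    """Reaction lowered onto (gene bits, protein counts) coordinates."""

    rate: float
    req: tuple[tuple[int, int], ...]  # required gene states
    flips: tuple[tuple[int, int], ...]  # gene -> new state
    orders: tuple[tuple[int, int], ...]  # protein position -> ff order
    deltas: tuple[tuple[int, int], ...]  # protein position -> count jump
    burst: tuple[int, float] | None  # (protein position, mean burst size)


def _lower_reactions(system: ReactionSystem, reactions=None) -> list[_RxView]:
    ind = {}
    for j, (off, on) in enumerate(system.gene_state_pairs):
        ind[off] = (j, 0)
        ind[on] = (j, 1)
    prot_pos = {s: i for i, s in enumerate(system.protein_of_gene)}
    views = []
    for r in reactions if reactions is not None else system.reactions:
        if r.mm is not None:
            raise MomentError(
                f"reaction {r.name!r} has a Michaelis-Menten propensity; "
                "moment equations are only derived for combinatorial "
                "(falling-factorial) propensities"
            )
        req, orders = [], []
        for s, h in r.orders:
            if s in ind:
                if h != 1:
                    raise MomentError(f"indicator order > 1 in {r.name!r}")
                req.append(ind[s])
            elif s in prot_pos:
                orders.append((prot_pos[s], h))
            else:
                raise MomentError(
                    f"reaction {r.name!r} involves species "
                    f"{system.species[s]!r} outside the gene/protein set; "
                    "moment derivation supports transcriptional networks only"
                )
        flips, deltas = [], []
        for s, dl in r.stoich:
            if s in ind:
                j, v = ind[s]
                if dl == 1:
                    flips.append((j, v))
            elif s in prot_pos:
                deltas.append((prot_pos[s], dl))
            else:
                raise MomentError(
                    f"reaction {r.name!r} changes non-protein species "
                    f"{system.species[s]!r}"
                )
        burst = None
        if r.burst_species >= 0:
            b = r.burst_p / (1.0 - r.burst_p)
            burst = (prot_pos[r.burst_species], b)
        views.append(_RxView(r.rate, tuple(req), tuple(flips), tuple(orders),
                             tuple(deltas), burst))
    return views


def _species_factor(h: int, m: int, delta: int, burst_mean: float | None):
    """(n)_h * (shifted feature factor of order m) as {order: coef}."""
    if burst_mean is not None:
        return ff.prod_ff_burst(h, m, burst_mean)
    if delta == 0 and (h == 0 or m == 0):
        return {h + m: 1.0}
    return ff.prod_ff_shift(h, m, delta)


def _expand(view: _RxView, m: tuple[int, ...], post: bool) -> dict[tuple[int, ...], float]:
    """Expectation of propensity x feature-factor as {multi-order: coef}.

    ``post`` selects the post-jump feature value (gain term) versus the
    pre-jump value (loss term).
    """
    n = len(m)
    hs = dict(view.orders)
    ds = dict(view.deltas) if post else {}
    bpos = view.burst[0] if (post and view.burst) else None
    combo: dict[tuple[int, ...], float] = {(): 1.0}
    for i in range(n):
        fac = _species_factor(
            hs.get(i, 0), m[i], ds.get(i, 0),
            view.burst[1] if bpos == i else None,
        )
        combo = {
            pref + (k,): c * cv for pref, c in combo.items() for k, cv in fac.items()
        }
    return {k: v * view.rate for k, v in combo.items() if v != 0.0}


def moment_matrix(system: ReactionSystem, basis: MomentBasis, reactions=None) -> sp.csr_matrix:
    """Assemble d(mu)/dt = A mu for the given reaction subset.

    Rows cover the main basis (|m| <= K), columns the extended basis so
    that unclosed contributions are visible; shape (n_main, n_ext).
    """
    views = _lower_reactions(system, reactions)
    acc: dict[tuple[int, int], float] = {}
    for v in views:
        for s in basis.states_matching(v.req):
            s2 = s
            for j, val in v.flips:
                s2 = (s2 & ~(1 << j)) | (val << j)
            for m in basis.orders[: basis.n_orders_main]:
                for mm, c in _expand(v, m, post=True).items():
                    key = (basis.col(s2, m), basis.col(s, mm))
                    acc[key] = acc.get(key, 0.0) + c
                for mm, c in _expand(v, m, post=False).items():
                    key = (basis.col(s, m), basis.col(s, mm))
                    acc[key] = acc.get(key, 0.0) - c
    if acc:
        keys = np.array(list(acc.keys()))
        vals = np.array(list(acc.values()))
        keep = np.abs(vals) > 1e-14
        a = sp.coo_matrix(
            (vals[keep], (keys[keep, 0], keys[keep, 1])),
            shape=(basis.n_main, basis.n_ext),
        )
    else:
        a = sp.coo_matrix((basis.n_main, basis.n_ext))
    return a.tocsr()


# ---------------------------------------------------------------------------
# moment expressions (used by the matching equations)


@dataclass(frozen=True)
class MomentTerm:
    """coef * E[ prod (n_i)_{orders_i} ; gene conditions ]."""

    coef: float
    cond: tuple[tuple[int, int], ...]
    orders: tuple[tuple[int, int], ...]  # protein position -> order


def flux_terms(system: ReactionSystem, reactions, cond, orders) -> list[MomentTerm]:
    """Expand sum_r E[a_r (f(x') - f(x))] for the feature
    f = 1{gene conditions} * prod (n_i)_{orders_i} into moment terms.

    ``cond`` is a tuple of (gene, state) pairs; ``orders`` maps protein
    *positions* to falling-factorial orders.
    """
    views = _lower_reactions(system, reactions)
    m_feat = dict(orders)
    nprot = len(system.protein_of_gene)
    mvec = tuple(m_feat.get(i, 0) for i in range(nprot))
    out: list[MomentTerm] = []
    for v in views:
        for post in (True, False):
            # combined gene condition: propensity requirement plus the
            # feature condition evaluated pre/post flip
            combined = dict(v.req)
            ok = True
            flips = dict(v.flips)
            for j, want in cond:
                if post and j in flips:
                    ok = ok and flips[j] == want
                else:
                    ok = ok and combined.setdefault(j, want) == want
                if not ok:
                    break
            if not ok:
                continue
            sign = 1.0 if post else -1.0
            for mm, c in _expand(v, mvec, post=post).items():
                out.append(
                    MomentTerm(
                        sign * c,
                        tuple(sorted(combined.items())),
                        tuple((i, k) for i, k in enumerate(mm) if k > 0),
                    )
                )
    return _merge_terms(out)


def _merge_terms(terms: list[MomentTerm]) -> list[MomentTerm]:
    acc: dict[tuple, float] = {}
    for t in terms:
        key = (t.cond, t.orders)
        acc[key] = acc.get(key, 0.0) + t.coef
    return [
        MomentTerm(c, cond, orders)
        for (cond, orders), c in acc.items()
        if abs(c) > 1e-14
    ]


# ---------------------------------------------------------------------------
# moment state


class ConditionalMomentState:
    """Vector of conditional factorial moments over a :class:`MomentBasis`."""

    def __init__(self, basis: MomentBasis, vec: np.ndarray, time: float | None = None):
        if len(vec) not in (basis.n_main, basis.n_ext):
            raise ValueError("vector length does not match basis")
        self.basis = basis
        self.vec = np.asarray(vec, dtype=float)
        self.time = time

    @classmethod
    def initial(cls, basis: MomentBasis, state: int = 0,
                counts=None) -> "ConditionalMomentState":
        """Point initial condition: joint gene state ``state`` and
        deterministic protein counts (default all zero)."""
        v = np.zeros(basis.n_main)
        if counts is None:
            counts = [0] * basis.n_genes
        for i in range(basis.n_orders_main):
            m = basis.orders[i]
            val = 1.0
            for pos, order in enumerate(m):
                for k in range(order):
                    val *= counts[pos] - k
            v[basis.col(state, m)] = val
        return cls(basis, v)

    @classmethod
    def single_gene(cls, g0: float, g1: float, mu: dict[tuple[int, int], float],
                    K: int | None = None) -> "ConditionalMomentState":
        """Build a one-gene state from {(order, gene_state): value}."""
        if K is None:
            K = max((o for o, _s in mu), default=1)
        basis = MomentBasis(1, K)
        v = np.zeros(basis.n_main)
        v[basis.col(0, (0,))] = g0
        v[basis.col(1, (0,))] = g1
        for (order, s), val in mu.items():
            v[basis.col(s, (order,))] = val
        return cls(basis, v)

    def g(self, s: int) -> float:
        zero = tuple([0] * self.basis.n_genes)
        return float(self.vec[self.basis.col(s, zero)])

    def g_gene(self, j: int, state: int) -> float:
        return self.expect({}, ((j, state),))

    def mu(self, m: tuple[int, ...], s: int) -> float:
        return float(self.vec[self.basis.col(s, m)])

    def expect(self, orders, cond=()) -> float:
        """E[ prod (n_i)_{orders_i} ; gene conditions ]; empty cond sums all."""
        od = dict(orders)
        m = tuple(od.get(i, 0) for i in range(self.basis.n_genes))
        total = 0.0
        for s in self.basis.states_matching(tuple(cond)):
            total += self.vec[self.basis.col(s, m)]
        return float(total)

    def eval_terms(self, terms: list[MomentTerm]) -> float:
        return sum(t.coef * self.expect(dict(t.orders), t.cond) for t in terms)

    def check_invariants(self, tol: float = 1e-6) -> None:
        gs = [self.g(s) for s in range(self.basis.n_states)]
        if abs(sum(gs) - 1.0) > tol:
            raise MomentError(f"gene-state probabilities sum to {sum(gs)}")
        if min(gs) < -tol:
            raise MomentError("negative gene-state probability")


def feature_row(basis: MomentBasis, orders, cond=()) -> np.ndarray:
    """Row vector r over the main basis with r @ mu = E[prod ff; cond]."""
    od = dict(orders)
    m = tuple(od.get(i, 0) for i in range(basis.n_genes))
    row = np.zeros(basis.n_main)
    for s in basis.states_matching(tuple(cond)):
        row[basis.col(s, m)] += 1.0
    return row


def terms_row(basis: MomentBasis, terms) -> np.ndarray:
    """Row vector over the main basis evaluating a moment-term sum."""
    row = np.zeros(basis.n_main)
    for t in terms:
        row += t.coef * feature_row(basis, dict(t.orders), t.cond)
    return row


class CachedMomentEvaluator:
    """Evaluator over a raw moment vector with per-closure row caching.

    Exposes the same ``expect``/``eval_terms``/``g_gene`` surface as
    :class:`ConditionalMomentState` but compiles every distinct query
    into a dot-product row the first time it is seen — the hot path of
    the self-consistent closure solve.
    """

    def __init__(self, basis: MomentBasis, vec: np.ndarray, cache: dict):
        self.basis = basis
        self.vec = vec
        self._cache = cache

    def expect(self, orders, cond=()) -> float:
        key = ("e", tuple(sorted(dict(orders).items())), tuple(cond))
        row = self._cache.get(key)
        if row is None:
            row = self._cache[key] = feature_row(self.basis, orders, cond)
        return float(row @ self.vec)

    def g_gene(self, j: int, state: int) -> float:
        return self.expect({}, ((j, state),))

    def eval_terms(self, terms) -> float:
        key = ("t", id(terms))
        row = self._cache.get(key)
        if row is None:
            row = self._cache[key] = terms_row(self.basis, terms)
        return float(row @ self.vec)


# ---------------------------------------------------------------------------
# moment system


@dataclass
class MomentSystem:
    """Linear moment evolution d(mu)/dt = A mu (+ spill onto higher orders)."""

    basis: MomentBasis
    A_main: sp.csr_matrix
    A_spill: sp.csr_matrix
    system: ReactionSystem
    network: GeneNetwork | None = None

    @property
    def closed(self) -> bool:
        return self.A_spill.nnz == 0

    @property
    def n_equations(self) -> int:
        """Independent equation count (the joint state probabilities carry
        one normalization redundancy)."""
        return self.basis.n_main - 1

    def rhs(self, vec: np.ndarray) -> np.ndarray:
        if not self.closed:
            raise MomentError(
                "moment system is not closed (references moments above order "
                f"{self.basis.K}); apply a mapping closure first"
            )
        return self.A_main @ vec


def derive_moment_system(network: GeneNetwork | ReactionSystem, K: int) -> MomentSystem:
    """Factorial-moment equations of a (possibly nonlinear) network.

    ``K`` must be at least h_max + 1, the order needed by the mapping
    step (which consumes moments of order h and h + 1).
    """
    if isinstance(network, GeneNetwork):
        net, system = network, compile_reactions(network)
    else:
        net, system = None, network
    h_max = max(
        (h for r in system.reactions for _s, h in r.orders if _s in system.protein_of_gene),
        default=1,
    )
    if net is not None:
        h_max = net.max_cooperativity
    if K < h_max + 1:
        raise MomentError(
            f"K = {K} too small: the mapping requires moments of order "
            f"h + 1 = {h_max + 1}"
        )
    basis = MomentBasis(len(system.gene_state_pairs), K, K + h_max)
    a = moment_matrix(system, basis)
    return MomentSystem(basis, a[:, : basis.n_main], a[:, basis.n_main:], system, net)


def integrate_moments(system: MomentSystem, init: ConditionalMomentState | np.ndarray,
                      t_grid, rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate a closed moment system over ``t_grid``.

    Returns a list of :class:`ConditionalMomentState`.  Uses a
    stiff-capable implicit integrator; raises on failure or NaN with the
    failing time attached.
    """
    vec0 = init.vec if isinstance(init, ConditionalMomentState) else np.asarray(init, float)
    a = system.A_main.toarray() if system.A_main.shape[0] <= 400 else system.A_main

    def rhs(_t, v):
        return a @ v

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), vec0, t_eval=t_grid, method="LSODA",
                    rtol=rtol, atol=atol,
                    jac=(lambda _t, _v: a) if isinstance(a, np.ndarray) else None)
    if not sol.success or not np.isfinite(sol.y).all():
        t_bad = sol.t[-1] if len(sol.t) else t_grid[0]
        raise MomentError(f"moment integration failed near t = {t_bad}: {sol.message}")
    return [ConditionalMomentState(system.basis, sol.y[:, k], float(t_grid[k]))
            for k in range(len(t_grid))]


def steady_state_moments(system: MomentSystem, tol: float = 1e-8,
                         init: ConditionalMomentState | None = None,
                         max_doublings: int = 8) -> ConditionalMomentState:
    """Steady state by long-time integration with a residual criterion.

    Integrates to t = 50 / d_min and doubles the horizon until the RHS
    infinity-norm (relative to the state scale) drops below ``tol``.
    """
    if init is None:
        init = ConditionalMomentState.initial(system.basis)
    d_min = 1.0
    if system.network is not None:
        d_min = min(g.d for g in system.network.genes) or 1.0
    horizon = 50.0 / d_min
    state = init
    for _ in range(max_doublings):
        state = integrate_moments(system, state, [0.0, horizon], rtol=1e-10, atol=1e-12)[-1]
        resid = np.max(np.abs(system.rhs(state.vec)))
        scale = max(1.0, np.max(np.abs(state.vec)))
        if resid / scale < tol:
            state.time = None
            return state
        horizon *= 2
    raise MomentError(f"steady state not reached: residual {resid / scale:.2e} > {tol}")


# ---------------------------------------------------------------------------
# brute-force CME oracle


def moments_of_vector(basis: MomentBasis, state_space, p: np.ndarray,
                      extended: bool = True) -> np.ndarray:
    """Moment vector of a truncated-CME probability vector."""
    counts = state_space.counts
    system = state_space.system
    bits = np.zeros(len(p), dtype=np.int64)
    for j, (_off, on) in enumerate(system.gene_state_pairs):
        bits |= counts[:, on].astype(np.int64) << j
    prots = [counts[:, s].astype(float) for s in system.protein_of_gene]
    n_ord = len(basis.orders) if extended else basis.n_orders_main
    out = np.zeros(basis.n_ext if extended else basis.n_main)
    for i in range(n_ord):
        m = basis.orders[i]
        feat = np.ones(len(p))
        for pos, order in enumerate(m):
            for k in range(order):
                feat = feat * (prots[pos] - k)
        w = feat * p
        for s in range(basis.n_states):
            out[basis.col(s, m)] = w[bits == s].sum()
    return out


def rhs_oracle_check(moment_system: MomentSystem, reaction_system: ReactionSystem,
                     n_max: int = 200, n_probes: int = 5, seed: int = 0) -> float:
    """Max deviation between the derived moment RHS and the brute-force
    truncated-CME generator, over random interior probability vectors.

    The probe vectors are supported on counts <= n_max / 2 so that no
    probability flows across the truncation boundary and the comparison
    is exact up to floating-point error.
    """
    if n_max < 64:
        raise MomentError("truncation too small for an interior-support check")
    caps = {s: n_max for s in reaction_system.protein_of_gene}
    q, ss = build_generator(reaction_system, caps)
    basis = moment_system.basis
    rng = np.random.default_rng(seed)
    interior = np.ones(ss.n_states, dtype=bool)
    for s in reaction_system.protein_of_gene:
        interior &= ss.counts[:, s] <= n_max // 2
    a_full = sp.hstack([moment_system.A_main, moment_system.A_spill]).tocsr()
    worst = 0.0
    for _ in range(n_probes):
        p = rng.random(ss.n_states) * interior
        # exponential tilt keeps the probe mass at realistic copy numbers
        for s in reaction_system.protein_of_gene:
            p = p * np.exp(-ss.counts[:, s] / 12.0)
        p /= p.sum()
        mu_ext = moments_of_vector(basis, ss, p, extended=True)
        lhs = a_full @ mu_ext
        qp = q @ p
        rhs = moments_of_vector(basis, ss, qp, extended=False)
        worst = max(worst, float(np.max(np.abs(lhs - rhs))))
    return worst
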