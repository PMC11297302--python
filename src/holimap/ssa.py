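"""Exact stochastic simulation (Gillespie direct method) of reaction systems.

Trajectories are sampled exactly: two uniform random numbers per event
choose the waiting time and the reaction channel; bursty synthesis
channels additionally draw a geometric jump size k with
``P(k = n) = p^n (1 - p)``.  States are recorded by interpolation at the
requested grid times (the state is piecewise constant between events, so
this is exact for jump processes).

Each trajectory runs on its own seeded RNG stream derived from
``(seed, trajectory index)`` so ensembles are bitwise reproducible and
trajectories are independent.  The inner loops are numba-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import ReactionSystem
from .linear_solver import DistributionOnCounts
from .moments import ConditionalMomentState


class SSAError(RuntimeError):
    pass


def sample_geometric_burst(p: float, rng: np.random.Generator) -> int:
    """One geometric burst size, support {0, 1, 2, ...}, mean p / (1 - p)."""
    if not 0.0 <= p < 1.0:
        raise SSAError(f"geometric parameter p must lie in [0, 1), got {p}")
    if p == 0.0:
        return 0
    return int(rng.geometric(1.0 - p)) - 1


@dataclass
class TrajectoryEnsemble:
    """N recorded trajectories of one reaction system.

    ``counts`` has shape (N, T, S): per-trajectory species counts at the
    recording grid times.
    """

    system: ReactionSystem
    t_grid: np.ndarray
    counts: np.ndarray
    seed: int

    @property
    def n_traj(self) -> int:
        return self.counts.shape[0]

    def time_index(self, t: float) -> int:
        k = int(np.argmin(np.abs(self.t_grid - t)))
        if abs(self.t_grid[k] - t) > 1e-9 * max(1.0, abs(t)):
            raise SSAError(f"time {t} is not on the recording grid")
        return k

    def at(self, t: float) -> np.ndarray:
        """(N, S) count matrix at a recorded time."""
        return self.counts[:, self.time_index(t), :]


@njit(cache=True)
def _run_trajectory(x, t_grid, rate, orders, stoich, burst_sp, burst_p,
                    mm_sub, mm_K, out):
    T = t_grid.shape[0]
    R = rate.shape[0]
    S = x.shape[0]
    a = np.empty(R)
    t = t_grid[0]
    gi = 0
    while gi < T:
        atot = 0.0
        for r in range(R):
            v = rate[r]
            for s in range(S):
                h = orders[r, s]
                for k in range(h):
                    v *= x[s] - k
            if mm_sub[r] >= 0:
                v *= x[mm_sub[r]] / (mm_K[r] + x[mm_sub[r]])
            if v < 0.0:
                v = 0.0
            a[r] = v
            atot += v
        if atot <= 0.0:
            while gi < T:
                for s in range(S):
                    out[gi, s] = x[s]
                gi += 1
            return
        tau = -math.log(np.random.random()) / atot
        t_next = t + tau
        while gi < T and t_grid[gi] < t_next:
            for s in range(S):
                out[gi, s] = x[s]
            gi += 1
        if gi >= T:
            return
        t = t_next
        u = np.random.random() * atot
        cum = 0.0
        rsel = R - 1
        for r in range(R):
            cum += a[r]
            if u <= cum:
                rsel = r
                break
        for s in range(S):
            x[s] += stoich[rsel, s]
        if burst_sp[rsel] >= 0:
            p = burst_p[rsel]
            if p > 0.0:
                u2 = np.random.random()
                while u2 <= 0.0:
                    u2 = np.random.random()
                x[burst_sp[rsel]] += int(math.floor(math.log(u2) / math.log(p)))


@njit(cache=True)
def _run_ensemble(x0, t_grid, rate, orders, stoich, burst_sp, burst_p,
                  mm_sub, mm_K, seeds, out):
    for i in range(seeds.shape[0]):
        np.random.seed(seeds[i])
        x = x0.copy()
        _run_trajectory(x, t_grid, rate, orders, stoich, burst_sp, burst_p,
                        mm_sub, mm_K, out[i])


def _encode(system: ReactionSystem):
    R, S = len(system.reactions), system.n_species
    rate = np.zeros(R)
    orders = np.zeros((R, S), dtype=np.int32)
    stoich = np.zeros((R, S), dtype=np.int64)
    burst_sp = np.full(R, -1, dtype=np.int32)
    burst_p = np.zeros(R)
    mm_sub = np.full(R, -1, dtype=np.int32)
    mm_K = np.zeros(R)
    for i, r in enumerate(system.reactions):
        rate[i] = r.rate
        for s, h in r.orders:
            orders[i, s] = h
        for s, dl in r.stoich:
            stoich[i, s] = dl
        if r.burst_species >= 0:
            burst_sp[i] = r.burst_species
            burst_p[i] = r.burst_p
        if r.mm is not None:
            mm_sub[i], mm_K[i] = r.mm[0], r.mm[1]
    return rate, orders, stoich, burst_sp, burst_p, mm_sub, mm_K


def simulate_ensemble(system: ReactionSystem, N: int, t_grid, seed: int,
                      init: np.ndarray | None = None) -> TrajectoryEnsemble:
    """N independent exact trajectories recorded at ``t_grid``.

    Fully reproducible: trajectory i uses a stream seeded from
    ``(seed, i)`` via a SeedSequence spawn.
    """
    if N < 1:
        raise SSAError(f"N must be >= 1, got {N}")
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise SSAError("t_grid must be strictly increasing")
    for r in system.reactions:
        if r.rate < 0:
            raise SSAError(f"negative rate in reaction {r.name!r}")
    x0 = (system.initial_counts() if init is None else np.asarray(init)).astype(np.int64)
    seeds = np.random.SeedSequence(seed).generate_state(N, dtype=np.uint64)
    seeds = (seeds % np.uint64(2**31 - 1)).astype(np.int64) + 1
    out = np.zeros((N, len(t_grid), system.n_species), dtype=np.int64)
    args = _encode(system)
    _run_ensemble(x0, t_grid, *args, seeds, out)
    return TrajectoryEnsemble(system, t_grid, out, seed)


def empirical_distribution(ensemble: TrajectoryEnsemble, species, t) -> DistributionOnCounts:
    """Normalized count histogram of one species at a recorded time."""
    system = ensemble.system
    s = system.species_index(species) if isinstance(species, str) else int(species)
    if not 0 <= s < system.n_species:
        raise SSAError(f"unknown species index {s}")
    col = ensemble.at(t)[:, s]
    h = np.bincount(col, minlength=max(int(col.max()) + 1, 2)).astype(float)
    return DistributionOnCounts(h / h.sum(), system.species[s], float(t))


def sample_conditional_moments(ensemble: TrajectoryEnsemble, gene: int, t,
                               order: int = 2, species: int | None = None
                               ) -> ConditionalMomentState:
    """Sample conditional factorial moments for one gene at one time.

    Returns a single-gene moment state: ``g_s`` are the gene-state
    frequencies and ``mu_{m,s}`` the averaged falling factorials of the
    chosen species (default: the gene's own protein) over trajectories
    in state s.
    """
    if order < 0:
        raise SSAError("order must be >= 0")
    system = ensemble.system
    counts = ensemble.at(t)
    off, on = system.gene_state_pairs[gene]
    sp = system.protein_of_gene[gene] if species is None else species
    state = counts[:, on]
    n = counts[:, sp].astype(float)
    N = len(state)
    mu = {}
    g = [float((state == s).sum()) / N for s in (0, 1)]
    ff = np.ones(N)
    for m in range(1, order + 1):
        ff = ff * (n - (m - 1))
        for s in (0, 1):
            mu[(m, s)] = float(ff[state == s].sum()) / N
    return ConditionalMomentState.single_gene(g[0], g[1], mu, K=max(order, 1))
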