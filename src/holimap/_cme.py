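"""Truncated chemical-master-equation generators by direct state enumeration.

This is the brute-force counterpart to the moment calculus: every reachable
state inside a rectangular truncation is enumerated and the CME generator
``Q`` is assembled so that ``dp/dt = Q p``.  Probability flowing out of the
truncation is discarded (the diagonal keeps the full outflow rate), which
gives the standard finite-state-projection behaviour: ``1 - sum(p)`` bounds
the truncation error.

Gene indicator pairs are enumerated as single bits; all other species get a
0..cap count range.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .model import ReactionSystem

_GEOM_TAIL = 1e-12


class StateSpace:
    """Rectangular truncated state space of a reaction system."""

    def __init__(self, system: ReactionSystem, caps: dict[int, int]):
        self.system = system
        pairs = system.gene_state_pairs
        indicator = {s for pair in pairs for s in pair}
        self.free = [s for s in range(system.n_species) if s not in indicator]
        missing = [s for s in self.free if s not in caps]
        if missing:
            names = [system.species[s] for s in missing]
            raise ValueError(f"no truncation cap for species {names}")
        self.caps = np.array([caps[s] for s in self.free], dtype=np.int64)
        self.dims = tuple([2] * len(pairs) + [int(c) + 1 for c in self.caps])
        self.n_states = int(np.prod(self.dims))
        digits = np.unravel_index(np.arange(self.n_states), self.dims)
        counts = np.zeros((self.n_states, system.n_species), dtype=np.int64)
        for b, (off, on) in enumerate(pairs):
            counts[:, on] = digits[b]
            counts[:, off] = 1 - digits[b]
        for i, s in enumerate(self.free):
            counts[:, s] = digits[len(pairs) + i]
        self.counts = counts
        self._strides = np.array(
            [int(np.prod(self.dims[i + 1:])) for i in range(len(self.dims))],
            dtype=np.int64,
        )

    def index_of(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map count vectors (batch, S) -> (flat index, validity mask)."""
        pairs = self.system.gene_state_pairs
        G = len(pairs)
        digs = np.empty((counts.shape[0], len(self.dims)), dtype=np.int64)
        ok = np.ones(counts.shape[0], dtype=bool)
        for b, (off, on) in enumerate(pairs):
            bit = counts[:, on]
            digs[:, b] = bit
            ok &= (bit >= 0) & (bit <= 1) & (counts[:, off] == 1 - bit)
        for i, s in enumerate(self.free):
            c = counts[:, s]
            digs[:, G + i] = c
            ok &= (c >= 0) & (c <= self.caps[i])
        idx = digs @ self._strides
        return idx, ok

    def marginal(self, p: np.ndarray, species: int) -> np.ndarray:
        """Marginal probability vector of one free species."""
        i = self.free.index(species)
        return np.bincount(
            self.counts[:, species], weights=p, minlength=int(self.caps[i]) + 1
        )

    def gene_state_probs(self, p: np.ndarray) -> np.ndarray:
        """Joint gene-state probabilities, indexed by the bit pattern."""
        pairs = self.system.gene_state_pairs
        code = np.zeros(self.n_states, dtype=np.int64)
        for b, (_off, on) in enumerate(pairs):
            code |= self.counts[:, on] << b
        return np.bincount(code, weights=p, minlength=2 ** len(pairs))


def _burst_weights(p: float, max_total: int) -> np.ndarray:
    """Geometric jump-size weights p^k (1-p) for k = 1.. until the tail
    drops below a fixed tolerance (or the truncation cap is hit)."""
    if p <= 0:
        return np.zeros(0)
    ks = []
    w = p * (1.0 - p)
    k = 1
    while w > _GEOM_TAIL and k <= max_total:
        ks.append(w)
        w *= p
        k += 1
    return np.array(ks)


def build_generator(system: ReactionSystem, caps: dict[int, int]) -> tuple[sp.csr_matrix, StateSpace]:
    """Assemble the truncated CME generator Q (dp/dt = Q p)."""
    ss = StateSpace(system, caps)
    n = ss.n_states
    counts = ss.counts
    src_all = np.arange(n)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for r in system.reactions:
        a = r.propensity(counts)
        live = a > 0
        if not live.any():
            continue
        a = a[live]
        src = src_all[live]
        base = counts[live].copy()
        for s, delta in r.stoich:
            base[:, s] += delta
        if r.burst_species >= 0:
            cap = int(max(ss.caps)) if len(ss.caps) else 0
            w = _burst_weights(r.burst_p, cap + 1)
            # outflow only for k >= 1 (a zero-size burst changes nothing)
            diag[src] -= a * r.burst_p
            dest_counts = base
            for k, wk in enumerate(w, start=1):
                dest_counts = base.copy()
                dest_counts[:, r.burst_species] += k
                idx, ok = ss.index_of(dest_counts)
                rows.append(idx[ok])
                cols.append(src[ok])
                vals.append(a[ok] * wk)
        else:
            diag[src] -= a
            idx, ok = ss.index_of(base)
            rows.append(idx[ok])
            cols.append(src[ok])
            vals.append(a[ok])
    if rows:
        q = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        q = sp.coo_matrix((n, n))
    return (q + sp.diags(diag)).tocsr(), ss
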