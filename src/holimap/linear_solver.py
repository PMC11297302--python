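"""Finite state projection solvers for linear (telegraph-type) gene models.

The effective linear network produced by the mapping step decouples into
independent single-gene telegraph models: a two-state gene switching at
rates ``sigma_b`` (off -> on) / ``sigma_u`` (on -> off), synthesising
protein at burst frequency ``rho0``/``rho1`` per state (geometric bursts
with parameter ``p``, or single molecules when ``p = 0``) and degrading it
at rate ``d``.  :func:`fsp_steady` and :func:`fsp_transient` solve this
model on an adaptively chosen truncation; :func:`fsp_nonlinear` applies
FSP directly to a full nonlinear reaction system and serves as the
ground-truth oracle for one- and two-gene networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from ._cme import StateSpace, build_generator
from .model import Reaction, ReactionSystem

DEFAULT_TOL = 1e-8
#: refuse direct nonlinear FSP beyond this many truncated states
STATE_SPACE_CAP = 2_000_000


class FSPError(RuntimeError):
    pass


@dataclass
class DistributionOnCounts:
    """Probability vector over molecule counts n = 0..N_max."""

    probs: np.ndarray
    species: str = "P"
    time: float | None = None
    eps: float = 0.0  # truncation deficit bound, 1 - sum(probs)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or len(self.probs) < 2:
            raise ValueError("probs must be a 1-D vector with N_max >= 1")
        if (self.probs < -1e-12).any():
            raise ValueError("negative probabilities")

    @property
    def n_max(self) -> int:
        return len(self.probs) - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probs))

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def variance(self) -> float:
        m = self.mean()
        return float((self.support.astype(float) ** 2) @ self.probs - m * m)

    def normalized(self) -> "DistributionOnCounts":
        p = np.clip(self.probs, 0.0, None)
        return DistributionOnCounts(p / p.sum(), self.species, self.time, self.eps)


def choose_truncation(mean: float, sd: float, safety: float = 10.0) -> int:
    """Initial truncation bound N_max = max(64, ceil(mean + safety * sd))."""
    if not (np.isfinite(mean) and np.isfinite(sd)):
        raise ValueError("mean and sd must be finite")
    return max(64, int(math.ceil(mean + safety * sd)))


def _telegraph_system(sigma_b, sigma_u, rho0, rho1, d, p) -> ReactionSystem:
    reactions = []
    if sigma_b > 0:
        reactions.append(Reaction("on", sigma_b, ((0, 1),), ((0, -1), (1, 1)),
                                  gene_flip=(0, 0, 1)))
    if sigma_u > 0:
        reactions.append(Reaction("off", sigma_u, ((1, 1),), ((0, 1), (1, -1)),
                                  gene_flip=(0, 1, 0)))
    for state, rho in ((0, rho0), (1, rho1)):
        if rho > 0:
            if p > 0:
                reactions.append(Reaction(f"burst{state}", rho, ((state, 1),), (),
                                          burst_species=2, burst_p=p))
            else:
                reactions.append(Reaction(f"syn{state}", rho, ((state, 1),), ((2, 1),)))
    if d > 0:
        reactions.append(Reaction("decay", d, ((2, 1),), ((2, -1),)))
    return ReactionSystem(["G", "G*", "P"], reactions, [(0, 1)], [2], name="telegraph")


def _params_tuple(params):
    """Accept either a LinearGeneParams-like object or a mapping."""
    if hasattr(params, "sigma_b"):
        return (params.sigma_b, params.sigma_u, params.rho0, params.rho1,
                params.d, getattr(params, "p", 0.0))
    return (params["sigma_b"], params["sigma_u"], params["rho0"], params["rho1"],
            params["d"], params.get("p", 0.0))


def _telegraph_moment_guess(sigma_b, sigma_u, rho0, rho1, d, p):
    tot = sigma_b + sigma_u
    g1 = sigma_b / tot if tot > 0 else 0.0
    B = p / (1.0 - p) if p > 0 else 1.0
    mean = B * (rho0 * (1 - g1) + rho1 * g1) / d if d > 0 else np.inf
    # crude overestimate of sd: demographic + burst + switching contributions
    spread = abs(rho1 - rho0) * B / max(d, 1e-12)
    sd = math.sqrt(max(mean, 1.0) * (1.0 + B)) + spread
    return mean, sd


def fsp_steady(params, tol: float = DEFAULT_TOL, max_doublings: int = 8,
               return_joint: bool = False):
    """Stationary protein distribution of the two-state bursty telegraph model.

    The truncation grows geometrically until the probability mass in the
    top 2% of the count range is below ``tol``.
    """
    sigma_b, sigma_u, rho0, rho1, d, p = _params_tuple(params)
    for name, v in (("sigma_b", sigma_b), ("sigma_u", sigma_u), ("rho0", rho0),
                    ("rho1", rho1), ("d", d)):
        if v < 0:
            raise FSPError(f"negative effective rate {name} = {v}")
    if d <= 0 and (rho0 > 0 or rho1 > 0):
        raise FSPError("no stationary distribution: zero degradation with synthesis")
    # an absorbing gene state makes the telegraph chain reducible; reduce to
    # the constitutive model of the absorbing state instead
    if sigma_b == 0 or sigma_u == 0:
        rho = rho0 if sigma_b == 0 else rho1
        dist = _constitutive_steady(rho, d, p, tol, max_doublings)
        if return_joint:
            joint = np.vstack([dist.probs, np.zeros_like(dist.probs)])
            if sigma_b > 0:
                joint = joint[::-1]
            return dist, joint
        return dist
    mean, sd = _telegraph_moment_guess(sigma_b, sigma_u, rho0, rho1, d, p)
    N = choose_truncation(mean, sd)
    system = _telegraph_system(sigma_b, sigma_u, rho0, rho1, d, p)
    for _ in range(max_doublings):
        q, ss = build_generator(system, {2: N})
        pvec = _steady_state_of(q)
        tail = pvec[ss.counts[:, 2] > 0.98 * N].sum()
        if tail < tol:
            marg = ss.marginal(pvec, 2)
            dist = DistributionOnCounts(np.clip(marg, 0, None), "P", None, eps=float(tail))
            if return_joint:
                joint = np.vstack([
                    np.bincount(ss.counts[pvec_mask, 2], weights=pvec[pvec_mask],
                                minlength=N + 1)
                    for pvec_mask in (ss.counts[:, 1] == 0, ss.counts[:, 1] == 1)
                ])
                return dist, joint
            return dist
        N *= 2
    raise FSPError(f"steady-state truncation did not converge (N = {N})")


def _constitutive_steady(rho, d, p, tol, max_doublings):
    reactions = []
    if rho > 0:
        if p > 0:
            reactions.append(Reaction("burst", rho, (), (), burst_species=0, burst_p=p))
        else:
            reactions.append(Reaction("syn", rho, (), ((0, 1),)))
    if d > 0:
        reactions.append(Reaction("decay", d, ((0, 1),), ((0, -1),)))
    system = ReactionSystem(["P"], reactions, [], [0], name="constitutive")
    B = p / (1 - p) if p > 0 else 1.0
    m = rho * B / d if d > 0 else 0.0
    N = choose_truncation(m, math.sqrt(max(m, 1.0) * (1 + B)))
    for _ in range(max_doublings):
        q, ss = build_generator(system, {0: N})
        pvec = _steady_state_of(q)
        tail = pvec[ss.counts[:, 0] > 0.98 * N].sum()
        if tail < tol:
            return DistributionOnCounts(ss.marginal(pvec, 0), "P", None, eps=float(tail))
        N *= 2
    raise FSPError("constitutive steady-state truncation did not converge")


def _steady_state_of(q: sp.csr_matrix) -> np.ndarray:
    """Stationary vector of a truncated generator (dp/dt = Q p).

    A reference state with substantial stationary mass is located by a
    few crude forward-Euler smoothing steps; its probability is pinned
    to 1 and the remaining sparsity-preserving linear system is solved
    with a fill-reducing ordering, then the result normalized.
    """
    n = q.shape[0]
    if n <= 2000:
        a = q.tolil()
        a[0, :] = 1.0
        b = np.zeros(n)
        b[0] = 1.0
        pvec = spla.spsolve(a.tocsc(), b)
        return np.clip(pvec, 0.0, None) / np.clip(pvec, 0.0, None).sum()
    v = np.full(n, 1.0 / n)
    dt = 0.5 / max(float(np.abs(q.diagonal()).max()), 1e-12)
    for _ in range(40):
        v = v + dt * (q @ v)
        v = np.clip(v, 0.0, None)
        v /= v.sum()
    k = int(np.argmax(v))
    scale = float(np.abs(q.diagonal()).max())
    qc = q.tocsc()

    def _residual_ok(pv):
        return np.abs(q @ pv).max() <= 1e-8 * max(scale, 1.0)

    try:
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        rhs = -np.asarray(qc[:, k].todense()).ravel()[keep]
        a = qc[keep][:, keep].tocsc()
        lu = spla.splu(a, permc_spec="MMD_AT_PLUS_A")
        x = lu.solve(rhs)
        pvec = np.empty(n)
        pvec[keep] = x
        pvec[k] = 1.0
        pvec = np.clip(pvec, 0.0, None)
        pvec /= pvec.sum()
        if _residual_ok(pvec):
            return pvec
    except RuntimeError:
        pass
    # the pinned solve can fail silently when the reference state carries
    # negligible stationary mass; redo with the (denser but well-posed)
    # normalization-row formulation
    a2 = q.tolil()
    a2[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    lu = spla.splu(a2.tocsc(), permc_spec="MMD_AT_PLUS_A")
    pvec = np.clip(lu.solve(b), 0.0, None)
    pvec /= pvec.sum()
    if not _residual_ok(pvec):
        raise FSPError("stationary solve failed: residual too large")
    return pvec


@dataclass
class ParamTrajectory:
    """Piecewise-linear effective-parameter trajectory for one gene."""

    times: np.ndarray
    sigma_b: np.ndarray
    sigma_u: np.ndarray
    rho0: np.ndarray
    rho1: np.ndarray
    d: float | np.ndarray
    p: float = 0.0
    flags: list = field(default_factory=list)

    def at(self, t: float):
        vals = [
            float(np.interp(t, self.times, v))
            for v in (self.sigma_b, self.sigma_u, self.rho0, self.rho1)
        ]
        d = self.d if np.isscalar(self.d) else float(np.interp(t, self.times, self.d))
        return (*vals, d)

    def d_min(self) -> float:
        return float(self.d) if np.isscalar(self.d) else float(np.min(self.d))

    def max_rates(self):
        return (self.sigma_b.max(), self.sigma_u.max(), self.rho0.max(), self.rho1.max())


def _constant_trajectory(params, t_grid) -> ParamTrajectory:
    sigma_b, sigma_u, rho0, rho1, d, p = _params_tuple(params)
    t = np.asarray([t_grid[0], t_grid[-1]], dtype=float)
    one = np.ones(2)
    return ParamTrajectory(t, sigma_b * one, sigma_u * one, rho0 * one, rho1 * one, d, p)


def fsp_transient(params_t, init, t_grid, tol: float = DEFAULT_TOL,
                  max_doublings: int = 5, rtol: float = 1e-8, atol: float = 1e-12):
    """Transient distributions of the telegraph model with time-dependent rates.

    ``params_t`` is a :class:`ParamTrajectory` (or constant parameters);
    rates between recorded times are linear interpolants.  ``init`` is a
    joint initial condition of shape (2, N+1) over (gene state, count),
    a marginal count distribution (placed in the unbound state), or None
    for the point mass at (off, 0).  Returns one distribution per output
    time; the probability deficit is checked at the final time and the
    truncation doubled on failure.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not isinstance(params_t, ParamTrajectory):
        params_t = _constant_trajectory(params_t, t_grid)
    sb, su, r0, r1 = params_t.max_rates()
    d, p = params_t.d_min(), params_t.p
    mean, sd = _telegraph_moment_guess(sb, su, r0, r1, max(d, 1e-9), p)
    N = choose_truncation(mean, sd)
    for _ in range(max_doublings):
        dists, deficit = _transient_once(params_t, init, t_grid, N, rtol, atol)
        if deficit < tol:
            return dists
        N *= 2
    raise FSPError(f"transient truncation did not converge: deficit {deficit:.2e} > {tol}")


def _transient_once(params_t: ParamTrajectory, init, t_grid, N, rtol, atol):
    p = params_t.p
    # unit-rate component generators; Q(t) is their rate-weighted sum
    comps = []
    for key in ("sigma_b", "sigma_u", "rho0", "rho1", "d"):
        kw = dict(sigma_b=0.0, sigma_u=0.0, rho0=0.0, rho1=0.0, d=0.0, p=p)
        kw[key] = 1.0
        comps.append(build_generator(_telegraph_system(**kw), {2: N})[0])
    _, ss = build_generator(_telegraph_system(1.0, 1.0, 0.0, 0.0, 0.0, p), {2: N})
    q_b, q_u, q_r0, q_r1, q_decay = comps

    p0 = np.zeros(ss.n_states)
    if init is None:
        idx, _ = ss.index_of(np.array([[1, 0, 0]]))
        p0[idx[0]] = 1.0
    else:
        arr = init.probs if isinstance(init, DistributionOnCounts) else np.asarray(init, float)
        if arr.ndim == 1:
            arr = np.vstack([arr, np.zeros_like(arr)])
        for state in (0, 1):
            m = min(arr.shape[1], N + 1)
            for n in range(m):
                if arr[state, n] > 0:
                    c = np.array([[1 - state, state, n]])
                    idx, ok = ss.index_of(c)
                    if ok[0]:
                        p0[idx[0]] += arr[state, n]

    def rhs(t, pv):
        sb, su, r0, r1, d = params_t.at(t)
        out = d * (q_decay @ pv)
        out += sb * (q_b @ pv)
        out += su * (q_u @ pv)
        if r0:
            out += r0 * (q_r0 @ pv)
        if r1:
            out += r1 * (q_r1 @ pv)
        return out

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), p0, t_eval=t_grid,
                    method="LSODA" if ss.n_states <= 600 else "RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise FSPError(f"transient FSP integration failed: {sol.message}")
    dists = []
    deficit = 0.0
    for k, t in enumerate(t_grid):
        pv = np.clip(sol.y[:, k], 0.0, None)
        deficit = max(deficit, 1.0 - pv.sum())
        dists.append(DistributionOnCounts(ss.marginal(pv, 2), "P", float(t),
                                          eps=float(max(1.0 - pv.sum(), 0.0))))
    return dists, deficit


def default_caps(system: ReactionSystem, network=None, safety: float = 10.0,
                 caps: dict[int, int] | None = None) -> dict[int, int]:
    """Heuristic truncation caps for a compiled transcriptional network."""
    if caps is not None:
        return caps
    if network is None:
        raise ValueError("caps must be given for non-transcriptional systems")
    out = {}
    for j, g in enumerate(network.genes):
        B = g.burst_size
        m = max(g.rho0, g.rho1) * B / g.d if g.d > 0 else 100.0
        sd = math.sqrt(max(m, 1.0) * (1.0 + B))
        out[system.protein_of_gene[j]] = max(32, int(math.ceil(m + safety * sd)))
    return out


def fsp_nonlinear(system: ReactionSystem, tol: float = DEFAULT_TOL, mode: str = "steady",
                  t_grid=None, caps: dict[int, int] | None = None, network=None,
                  species: int | None = None, max_doublings: int = 4):
    """Direct FSP of the full nonlinear CME (ground truth for small networks).

    Returns the marginal distribution of ``species`` (default: the first
    gene's protein) — a single distribution in steady mode, a list per
    output time in transient mode.  Raises when the truncated state space
    exceeds the documented cap; use the SSA for larger networks.
    """
    caps = default_caps(system, network, caps=caps)
    sp_idx = species if species is not None else system.protein_of_gene[0]
    for _ in range(max_doublings):
        n_states = 2 ** len(system.gene_state_pairs)
        for c in caps.values():
            n_states *= c + 1
        if n_states > STATE_SPACE_CAP:
            raise FSPError(
                f"truncated state space has {n_states} states (cap "
                f"{STATE_SPACE_CAP}); use the SSA / hybrid method instead"
            )
        q, ss = build_generator(system, caps)
        if mode == "steady":
            pvec = _steady_state_of(q)
            i = ss.free.index(sp_idx)
            tail = pvec[ss.counts[:, sp_idx] > 0.98 * ss.caps[i]].sum()
            if tail < tol:
                return DistributionOnCounts(ss.marginal(pvec, sp_idx), "P",
                                            None, eps=float(tail))
            caps = {s: 2 * c for s, c in caps.items()}
        elif mode == "transient":
            if t_grid is None:
                raise ValueError("transient mode requires t_grid")
            p0 = np.zeros(ss.n_states)
            idx, ok = ss.index_of(system.initial_counts()[None, :])
            if not ok[0]:
                raise FSPError("initial state outside truncation")
            p0[idx[0]] = 1.0
            t_grid = np.asarray(t_grid, dtype=float)
            dists = []
            pv = p0
            deficit_ok = True
            for k in range(len(t_grid)):
                dt = t_grid[k] - (t_grid[k - 1] if k else t_grid[0])
                if dt > 0:
                    pv = spla.expm_multiply(q * dt, pv)
                pvc = np.clip(pv, 0.0, None)
                if 1.0 - pvc.sum() > tol:
                    deficit_ok = False
                    break
                dists.append(DistributionOnCounts(ss.marginal(pvc, sp_idx), "P",
                                                  float(t_grid[k]),
                                                  eps=float(1.0 - pvc.sum())))
            if deficit_ok:
                return dists
            caps = {s: 2 * c for s, c in caps.items()}
        else:
            raise ValueError(f"unknown mode {mode!r}")
    raise FSPError("nonlinear FSP truncation did not converge")
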