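"""Hybrid SSA + Holimap: sample moments in, smooth distributions out.

The hybrid method runs a modest SSA ensemble (a few thousand
trajectories), estimates the conditional sample moments at every output
time, substitutes them into the moment-matching equations to obtain the
effective linear-network parameters, and finally solves each gene's
effective telegraph model by FSP.  The result is a smooth (noise-free)
distribution whose cost is dominated by the SSA stage, independent of the
number of genes, because the mapped linear network decouples per gene.

Missing data are handled conservatively: if a gene state was never
visited at some output time (so conditional moments are undefined), the
last valid effective parameters are carried forward; before any valid
instant exists, the LMA with unconditional moments is used.  No smoothing
is applied to the sample-moment time series by default.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .linear_solver import ParamTrajectory, fsp_steady, fsp_transient
from .mapping import (
    LinearGeneParams,
    MappingError,
    Matcher,
    SampleEvaluator,
    hm3_params,
)
from .model import GeneNetwork, ReactionSystem, compile_reactions
from .ssa import TrajectoryEnsemble, empirical_distribution, simulate_ensemble
from .analysis import hellinger


@dataclass
class HybridResult:
    method: str
    t_grid: np.ndarray
    params: list  # per gene: list of LinearGeneParams per time
    trajectories: list  # per gene: ParamTrajectory
    distributions: list  # per gene: list of DistributionOnCounts per time
    ensemble: TrajectoryEnsemble
    timings: dict = field(default_factory=dict)


def _valid(p: LinearGeneParams) -> bool:
    vals = (p.sigma_b, p.sigma_u, p.rho0, p.rho1, p.d)
    return all(np.isfinite(v) for v in vals) and min(vals) >= 0 and \
        "vanishing-state-probability" not in p.flags


def _lma_unconditional(matcher: Matcher, ev: SampleEvaluator, j: int) -> LinearGeneParams:
    """LMA-style rates from unconditional moments (start-up fallback when a
    gene state has never been visited)."""
    g = matcher.network.genes[j]
    sb = su = 0.0
    for direction, rate, orders, _cond in matcher._lma_channels[j]:
        eff = rate * ev.expect(orders, ()) if orders else rate
        if direction == "b":
            sb += eff
        else:
            su += eff
    return LinearGeneParams(j, sb, su, g.rho0, g.rho1, g.d, g.p,
                            method="lma", flags=("unconditional-lma",))


def _params_at(method, matcher, system, ev, stationary=False):
    if method == "hm3":
        return hm3_params(ev, system)
    if method == "hm4":
        return matcher.hm4_params(ev, clamp_negative=True, strict_lma=False,
                                  stationary=stationary)
    return matcher.hm2_params(ev, strict_lma=False, stationary=stationary)


def hybrid_solve(network, method: str = "hm2", N: int = 2000, t_grid=None,
                 seed: int = 0, mode: str = "transient", fsp_tol: float = 1e-8,
                 init=None, steady_window: float = 0.2, genes=None) -> HybridResult:
    """Three-stage SSA + Holimap solve.

    1. ``simulate_ensemble`` draws N exact trajectories of the nonlinear
       network; 2. sample conditional moments at each output time are
       substituted into the matching equations of the chosen method
       (``hm2``/``hm4`` for transcriptional networks, ``hm3`` for
       post-regulation reaction systems); 3. the decoupled effective
       telegraph models are solved by FSP (time-dependent rates in
       transient mode, late-window-averaged moments in steady mode).
    """
    if N < 2:
        raise MappingError(f"hybrid method needs N >= 2 trajectories, got {N}")
    method = method.lower()
    if method not in ("hm2", "hm3", "hm4"):
        raise MappingError(f"hybrid supports hm2/hm3/hm4, got {method!r}")
    if isinstance(network, GeneNetwork):
        system = compile_reactions(network)
    else:
        system, network = network, None
    if method in ("hm2", "hm4") and network is None:
        raise MappingError("hm2/hm4 hybrid requires a GeneNetwork")
    if method == "hm3" and network is not None:
        raise MappingError("hm3 applies to post-regulation ReactionSystems")
    t_grid = np.asarray(t_grid, dtype=float)
    t0 = time.perf_counter()
    ens = simulate_ensemble(system, N, t_grid, seed, init=init)
    t_ssa = time.perf_counter() - t0

    matcher = Matcher(network, method) if network is not None else None
    all_genes = range(len(system.gene_state_pairs))
    t0 = time.perf_counter()
    per_time: list[list[LinearGeneParams]] = []
    prev: list[LinearGeneParams | None] = [None] * len(system.gene_state_pairs)
    for k in range(len(t_grid)):
        ev = SampleEvaluator(ens.counts[:, k, :], system)
        try:
            ps = _params_at(method, matcher, system, ev)
        except MappingError:
            ps = [None] * len(system.gene_state_pairs)
        fixed = []
        for j in all_genes:
            p = ps[j] if ps[j] is not None and _valid(ps[j]) else None
            if p is None:
                if prev[j] is not None:
                    p = prev[j]
                    p = LinearGeneParams(j, p.sigma_b, p.sigma_u, p.rho0, p.rho1,
                                         p.d, p.p, method=method,
                                         flags=p.flags + ("carried-forward",))
                elif matcher is not None:
                    p = _lma_unconditional(matcher, ev, j)
                else:
                    raise MappingError(
                        f"gene {j}: no valid effective parameters at "
                        f"t = {t_grid[k]} and none to carry forward"
                    )
            fixed.append(p)
            prev[j] = p
        per_time.append(fixed)
    t_match = time.perf_counter() - t0

    solve_genes = set(range(len(system.gene_state_pairs))) if genes is None else set(genes)
    t0 = time.perf_counter()
    trajectories, dists, params = [], [], []
    if mode == "steady":
        k0 = max(0, int(np.ceil((1.0 - steady_window) * (len(t_grid) - 1))))
        pooled = ens.counts[:, k0:, :].reshape(-1, system.n_species)
        ev = SampleEvaluator(pooled, system)
        ps = _params_at(method, matcher, system, ev,
                        stationary=method != "hm3")
        for j in all_genes:
            p = ps[j].nonneg()
            params.append([p])
            trajectories.append(None)
            dists.append(fsp_steady(p, tol=fsp_tol) if j in solve_genes else None)
    elif mode == "transient":
        for j in all_genes:
            series = [pt[j].nonneg() for pt in per_time]
            d_arr = np.array([p.d for p in series])
            tr = ParamTrajectory(
                times=t_grid,
                sigma_b=np.array([p.sigma_b for p in series]),
                sigma_u=np.array([p.sigma_u for p in series]),
                rho0=np.array([p.rho0 for p in series]),
                rho1=np.array([p.rho1 for p in series]),
                d=d_arr if np.ptp(d_arr) > 0 else float(d_arr[0]),
                p=series[0].p,
            )
            init_j = None
            if init is not None:
                n0 = int(init[system.protein_of_gene[j]])
                if n0 > 0:
                    init_j = np.zeros((2, n0 + 1))
                    init_j[0, n0] = 1.0
            params.append(series)
            trajectories.append(tr)
            dists.append(fsp_transient(tr, init_j, t_grid, tol=fsp_tol)
                         if j in solve_genes else None)
    else:
        raise MappingError(f"unknown mode {mode!r}")
    t_fsp = time.perf_counter() - t0
    return HybridResult(method, t_grid, params, trajectories, dists, ens,
                        timings={"ssa": t_ssa, "matching": t_match, "fsp": t_fsp})


def sufficiency_check(network, N: int, t_grid, seed: int, ratio: int = 3,
                      threshold: float = 0.02, init=None, method: str = "hm2",
                      genes=(0,)):
    """Sample-size adequacy test for the hybrid method.

    Runs the full hybrid solve with N and with ``ratio * N`` independent
    trajectories and compares the resulting (smooth) distributions; if
    their time-averaged Hellinger distance is below the threshold,
    enlarging the ensemble would not substantially change the answer and
    N is declared sufficient.
    """
    if N < 2:
        raise MappingError(f"N must be >= 2, got {N}")
    t_grid = np.asarray(t_grid, dtype=float)
    s1, s2 = (int(x) for x in
              np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1))
    if ratio == 1:
        s2 = s1
    res_a = hybrid_solve(network, method, N=N, t_grid=t_grid, seed=s1,
                         init=init, genes=genes)
    res_b = hybrid_solve(network, method, N=ratio * N, t_grid=t_grid, seed=s2,
                         init=init, genes=genes)
    hds = []
    for j in genes:
        for k in range(1, len(t_grid)):
            pa = res_a.distributions[j][k].normalized()
            pb = res_b.distributions[j][k].normalized()
            hds.append(hellinger(pa, pb))
    avg = float(np.mean(hds))
    return avg, avg < threshold
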