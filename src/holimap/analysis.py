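"""Accuracy metrics, distribution-shape diagnostics and parameter sweeps.

The accuracy metric throughout is the Hellinger distance
``HD(p, q) = sqrt(1 - sum_n sqrt(p_n q_n))`` (one minus the Bhattacharyya
coefficient under the square root), bounded in [0, 1]; approximations with
HD well below 0.1 are visually indistinguishable from the reference.  The
alternative ``L2/sqrt(2)`` convention is deliberately not used.

Shape diagnostics: the Fano factor (variance over mean; 1 for a Poisson
distribution, 1 + B for constitutive expression with geometric bursts of
mean B) and a prominence-based mode counter used to delimit bimodal
parameter regions.

Sweeps: :func:`sweep_bimodal_region` maps HD and mode count over a
parameter grid against the nonlinear-FSP ground truth, and
:func:`autoreg_accuracy_battery` runs the standard steady-state accuracy
comparison (LMA vs 2-HM vs 4-HM) for the bursty autoregulatory loop.

Deterministic analysis: :func:`rate_equations` builds the mean-field ODEs
of a network and :func:`classify_determinism` labels the deterministic
dynamics monostable / bistable / oscillatory by multi-start fixed-point
enumeration plus Jacobian eigenvalues and a limit-cycle check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .linear_solver import DistributionOnCounts, fsp_nonlinear
from .mapping import holimap_solve
from .model import GeneNetwork, ReactionSystem, build_autoreg, compile_reactions


class AnalysisError(RuntimeError):
    pass


def _padded(p, q):
    n = max(len(p), len(q))
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: len(p)] = p
    qq[: len(q)] = q
    return pp, qq


def hellinger(p, q, tol: float = 1e-6) -> float:
    """Hellinger distance between two count distributions.

    Supports are zero-padded to a common length; inputs must be
    normalized within ``tol``.
    """
    p = p.probs if isinstance(p, DistributionOnCounts) else np.asarray(p, float)
    q = q.probs if isinstance(q, DistributionOnCounts) else np.asarray(q, float)
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > tol:
            raise AnalysisError(f"{name} is not normalized: sum = {v.sum()!r}")
    pp, qq = _padded(p, q)
    return float(math.sqrt(max(0.0, 1.0 - np.sum(np.sqrt(pp * qq)))))


def fano(dist) -> float:
    """Fano factor (variance / mean) of a count distribution."""
    if not isinstance(dist, DistributionOnCounts):
        dist = DistributionOnCounts(np.asarray(dist, float))
    m = dist.mean()
    if m <= 0:
        raise AnalysisError("Fano factor undefined: zero mean")
    return dist.variance() / m


def count_modes(dist, min_prominence: float = 1e-4) -> int:
    """Number of modes with prominence above ``min_prominence``.

    A mode is a local maximum (the boundary n = 0 included, plateaus
    merged into a single mode) whose height exceeds the higher of the two
    flanking minima by at least ``min_prominence``.  The default
    prominence suppresses truncation ripple without hiding genuinely
    shallow secondary modes.
    """
    p = dist.probs if isinstance(dist, DistributionOnCounts) else np.asarray(dist, float)
    # merge plateaus: strictly-increasing/decreasing runs decide maxima
    n = len(p)
    modes = 0
    i = 0
    prev_min = 0.0  # left flanking minimum (boundary counts as height 0)
    while i < n:
        # ascend (or start) to a local max
        j = i
        while j + 1 < n and p[j + 1] >= p[j]:
            j += 1
        # p[j] is a plateau/local max; descend to next local min
        k = j
        while k + 1 < n and p[k + 1] <= p[k]:
            k += 1
        next_min = p[k] if k + 1 < n else 0.0
        if p[j] - max(prev_min, next_min) > min_prominence:
            modes += 1
        prev_min = next_min
        i = k + 1 if k > i else i + 1
    return modes


def is_bimodal(dist, min_prominence: float = 1e-4) -> bool:
    return count_modes(dist, min_prominence) >= 2


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepResult:
    axes: tuple[np.ndarray, np.ndarray]
    hd: np.ndarray
    n_modes: np.ndarray
    bimodal: np.ndarray
    failures: list = field(default_factory=list)

    @property
    def max_hd(self) -> float:
        vals = self.hd[np.isfinite(self.hd)]
        return float(vals.max()) if len(vals) else float("nan")


def sweep_bimodal_region(network_factory, axis1, axis2, solver: str = "hm4",
                         species: int | None = None, min_prominence: float = 1e-4,
                         fsp_tol: float = 1e-8, max_failure_frac: float = 0.1) -> SweepResult:
    """Steady-state HD and bimodality mask over a 2-D parameter grid.

    ``network_factory(a, b)`` builds the network at grid point (a, b);
    ``solver`` is one of ``nonlinear_fsp``, ``lma``, ``hm2``, ``hm4``.
    Each point's distribution is compared against the nonlinear-FSP
    ground truth; per-point failures are recorded and tolerated up to
    ``max_failure_frac`` of the grid.
    """
    axis1 = np.asarray(axis1, float)
    axis2 = np.asarray(axis2, float)
    hd_grid = np.full((len(axis1), len(axis2)), np.nan)
    modes = np.zeros_like(hd_grid, dtype=int)
    failures = []
    for i, a in enumerate(axis1):
        for j, b in enumerate(axis2):
            net = network_factory(a, b)
            try:
                ref = fsp_nonlinear(compile_reactions(net), network=net, tol=fsp_tol,
                                    species=species)
                if solver == "nonlinear_fsp":
                    approx = ref
                elif solver.startswith("ssa+"):
                    # sample-moment (hybrid) mapping: steady moments from
                    # time-averaged long-run trajectories
                    from .hybrid import hybrid_solve

                    res = hybrid_solve(net, solver[4:], N=400,
                                       t_grid=np.linspace(0, 400, 201),
                                       seed=7, mode="steady", genes=[0],
                                       steady_window=0.5)
                    approx = res.distributions[0]
                else:
                    sol = holimap_solve(net, solver, "steady", fsp_tol=fsp_tol)
                    approx = sol.distributions[0]
                hd_grid[i, j] = hellinger(approx.normalized(), ref.normalized())
                modes[i, j] = count_modes(approx.normalized(), min_prominence)
            except Exception as exc:  # recorded, not fatal
                failures.append(((i, j), repr(exc)))
    if len(failures) > max_failure_frac * hd_grid.size:
        raise AnalysisError(
            f"{len(failures)} / {hd_grid.size} sweep points failed: "
            f"{failures[:3]}"
        )
    return SweepResult((axis1, axis2), hd_grid, modes, modes >= 2, failures)


def true_bimodal_mask(network_factory, axis1, axis2, species: int | None = None,
                      min_prominence: float = 1e-4) -> np.ndarray:
    """Bimodality mask of the nonlinear FSP ground truth over the grid."""
    res = sweep_bimodal_region(network_factory, axis1, axis2, "nonlinear_fsp",
                               species=species, min_prominence=min_prominence)
    return res.bimodal


# -- the standard autoregulation accuracy battery ---------------------------

#: positive-feedback battery defaults: burst frequencies with rho_b >> rho_u,
#: geometric bursts of mean 1, unit decay rate
BATTERY_RHO_U = 5.0
BATTERY_RHO_B = 50.0
BATTERY_P = 0.5


def _battery_g1(sigma_b, sigma_u, h):
    net = build_autoreg(sigma_b=sigma_b, sigma_u=sigma_u, rho_b=BATTERY_RHO_B,
                        rho_u=BATTERY_RHO_U, d=1.0, h=h, p=BATTERY_P)
    system = compile_reactions(net)
    from ._cme import build_generator
    from .linear_solver import _steady_state_of, default_caps

    q, ss = build_generator(system, default_caps(system, net))
    return ss.gene_state_probs(_steady_state_of(q))[1]


def binding_transition(sigma_u: float, h: int, xtol: float = 0.1) -> float:
    """Binding rate at which the bound-state probability crosses 1/2.

    Because an h-fold cooperative propensity scales with the h-th
    factorial moment of the regulator, comparable sweeps across
    cooperativities must express sigma_b relative to this transition
    point rather than on a fixed absolute scale.
    """
    f = lambda lsb: _battery_g1(10**lsb, sigma_u, h) - 0.5
    lo, hi = -8.0, 1.0
    while f(lo) > 0:
        lo -= 1
    while f(hi) < 0:
        hi += 1
    return 10 ** brentq(f, lo, hi, xtol=xtol)


def autoreg_accuracy_battery(h: int, n_su: int = 15, n_sb: int = 15,
                             methods=("lma", "hm2", "hm4"),
                             su_range=(1.0, 10.0), x_range=(0.02, 0.5)):
    """Max steady-state HD per method over the standard autoregulation grid.

    The grid covers the biologically typical fast-switching regime
    sigma_u/d in ``su_range`` and binding rates at ``x_range`` multiples
    of the per-(sigma_u, h) transition point.  Returns
    ({method: (max HD, HD grid)}, failures); isolated per-point solver
    failures are recorded and tolerated up to 10% of the grid.
    """
    sus = np.geomspace(*su_range, n_su)
    xs = np.geomspace(*x_range, n_sb)
    grids = {m: np.full((n_su, n_sb), np.nan) for m in methods}
    failures = []
    for i, su in enumerate(sus):
        tr = binding_transition(su, h)
        for j, x in enumerate(xs):
            net = build_autoreg(sigma_b=tr * x, sigma_u=su, rho_b=BATTERY_RHO_B,
                                rho_u=BATTERY_RHO_U, d=1.0, h=h, p=BATTERY_P)
            ref = fsp_nonlinear(compile_reactions(net), network=net).normalized()
            for m in methods:
                try:
                    sol = holimap_solve(net, m, "steady")
                    grids[m][i, j] = hellinger(sol.distributions[0].normalized(), ref)
                except Exception as exc:  # per-point failures recorded
                    failures.append(((m, i, j), repr(exc)))
    if len(failures) > 0.1 * n_su * n_sb * len(methods):
        raise AnalysisError(f"{len(failures)} battery points failed: {failures[:3]}")
    return {m: (float(np.nanmax(g)), g) for m, g in grids.items()}, failures


# ---------------------------------------------------------------------------
# deterministic rate equations


def rate_equations(network_or_system):
    """Mean-field ODE right-hand side of a reaction system.

    State: one concentration per non-indicator species plus one
    active-state fraction per gene.  Propensities are evaluated at the
    means with falling factorials replaced by plain powers; geometric
    burst channels contribute their mean burst size to the flux.
    Returns ``(rhs, labels)`` with ``rhs(x) -> dx/dt``.
    """
    system = (compile_reactions(network_or_system)
              if isinstance(network_or_system, GeneNetwork) else network_or_system)
    pairs = system.gene_state_pairs
    on_of = {on: g for g, (_off, on) in enumerate(pairs)}
    off_of = {off: g for g, (off, _on) in enumerate(pairs)}
    indicator = set(on_of) | set(off_of)
    free = [s for s in range(system.n_species) if s not in indicator]
    free_pos = {s: i for i, s in enumerate(free)}
    G = len(pairs)
    labels = [f"g*_{g+1}" for g in range(G)] + [system.species[s] for s in free]

    def expand(x):
        full = np.empty(system.n_species)
        for s, g in on_of.items():
            full[s] = x[g]
        for s, g in off_of.items():
            full[s] = 1.0 - x[g]
        for s, i in free_pos.items():
            full[s] = x[G + i]
        return full

    def rhs(x):
        full = expand(x)
        dx = np.zeros(G + len(free))
        for r in system.reactions:
            a = r.rate
            for s, h in r.orders:
                a *= full[s] ** h
            if r.mm is not None:
                s, K = r.mm
                a *= full[s] / (K + full[s])
            if a == 0.0:
                continue
            for s, dl in r.stoich:
                if s in on_of:
                    dx[on_of[s]] += dl * a
                elif s in free_pos:
                    dx[G + free_pos[s]] += dl * a
            if r.burst_species >= 0:
                B = r.burst_p / (1.0 - r.burst_p)
                dx[G + free_pos[r.burst_species]] += B * a
        return dx

    return rhs, labels


def _jacobian(rhs, x, eps=1e-6):
    n = len(x)
    f0 = rhs(x)
    jac = np.zeros((n, n))
    for i in range(n):
        dx = np.zeros(n)
        dx[i] = eps * max(1.0, abs(x[i]))
        jac[:, i] = (rhs(x + dx) - f0) / dx[i]
    return jac


def classify_determinism(network_or_system, n_starts: int = 40, seed: int = 0,
                         t_probe: float = 200.0) -> dict:
    """Classify the deterministic dynamics of a network.

    Multi-start root finding enumerates fixed points of the mean-field
    ODEs; Jacobian eigenvalues decide their stability.  Classification:
    ``bistable`` for two or more stable fixed points, ``oscillatory``
    when no fixed point is stable and a long integration shows sustained
    (non-decaying) oscillations, ``monostable`` otherwise;
    ``unclassified`` if root finding fails everywhere.
    """
    system = (compile_reactions(network_or_system)
              if isinstance(network_or_system, GeneNetwork) else network_or_system)
    rhs, labels = rate_equations(system)
    G = len(system.gene_state_pairs)
    n = len(labels)
    rng = np.random.default_rng(seed)
    # crude concentration scale from zero-order influx over unit decay
    scale = max(
        [r.rate * (1 + r.burst_p / (1 - r.burst_p)) for r in system.reactions
         if r.burst_species >= 0 or any(dl > 0 for _s, dl in r.stoich)] or [10.0]
    )
    fixed, stable = [], []
    for k in range(n_starts):
        x0 = np.empty(n)
        x0[:G] = rng.random(G)
        x0[G:] = rng.random(n - G) * scale * 1.5
        sol = root(rhs, x0, method="hybr")
        if not sol.success:
            continue
        x = sol.x
        if (x[:G] < -1e-6).any() or (x[:G] > 1 + 1e-6).any() or (x[G:] < -1e-6).any():
            continue
        if any(np.allclose(x, y, rtol=1e-4, atol=1e-6) for y in fixed):
            continue
        fixed.append(x)
        eig = np.linalg.eigvals(_jacobian(rhs, x))
        stable.append(bool(np.max(eig.real) < 1e-8))
    if not fixed:
        return {"class": "unclassified", "fixed_points": [], "stable": []}
    n_stable = sum(stable)
    result = {"class": "monostable", "fixed_points": fixed, "stable": stable,
              "labels": labels}
    if n_stable >= 2:
        result["class"] = "bistable"
        return result
    if n_stable == 0:
        # no stable fixed point: probe for a sustained limit cycle
        x0 = np.clip(fixed[0] + 0.1 * scale * rng.standard_normal(n), 0, None)
        x0[:G] = np.clip(x0[:G], 0, 1)
        traj = solve_ivp(lambda _t, x: rhs(x), (0, t_probe), x0, method="LSODA",
                         dense_output=False, rtol=1e-8, atol=1e-10,
                         t_eval=np.linspace(0.6 * t_probe, t_probe, 400))
        y = traj.y[G] if traj.y.shape[0] > G else traj.y[0]
        amp = y.max() - y.min()
        if amp > 1e-3 * max(1.0, y.mean()):
            result["class"] = "oscillatory"
            result["amplitude"] = float(amp)
    return result


# ---------------------------------------------------------------------------
# in-text arithmetic helpers


def protein_decay_rate_per_min(half_life_h: float = 46.0,
                               cell_cycle_h: float = 27.5) -> float:
    """Effective protein decay rate (degradation + dilution) in 1/min.

    d = ln2 / t_half + ln2 / t_cycle, converted from 1/h to 1/min —
    e.g. the mouse-fibroblast estimate of ~6.7e-4 per minute.
    """
    return (math.log(2) / half_life_h + math.log(2) / cell_cycle_h) / 60.0


def total_switching_rate(alpha: float, sigma: float, mean_regulator: float) -> float:
    """Total gene switching rate: spontaneous part plus regulation flux
    sigma times the mean regulator copy number."""
    return alpha + sigma * mean_regulator
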