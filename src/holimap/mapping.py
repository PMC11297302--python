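"""Linear-mapping approximations: LMA, 2-HM, 4-HM and 3-HM.

The mapping step replaces every nonlinear protein-gene binding reaction of
a regulatory network by an effective first-order gene switch, producing a
linear network whose genes decouple into independent telegraph models.
The effective rates are fixed by conditional moment-matching:

* **LMA** — the binding propensity is replaced by its conditional mean:
  ``sigma_b_hat = sigma_b * mu_{h,0} / g_0`` per protein-dependent switch
  channel; the unbinding/spontaneous rates are unchanged.
* **2-HM** — both switching rates of each regulated gene are replaced by
  ``(sigma_u~, sigma_b~)`` chosen so the linear and nonlinear networks
  share the gene-state (zeroth) and bound-state first-moment equations.
* **4-HM** — additionally replaces the two synthesis rates: first
  ``(rho0_bar, rho1_bar)`` are matched through the unconditional first-
  and second-moment equations, then ``(sigma_u_bar, sigma_b_bar)`` through
  the 2-HM equations with a synthesis-difference correction term.
* **3-HM** — for post-translational/post-transcriptional systems:
  switching rates as in the 2-HM plus an effective degradation rate that
  absorbs every bimolecular or enzymatic loss channel of the tracked
  species, ``d~ = d + sum_r E[a_r] * loss_r / E[n]``.

Matching equations are generated from the reaction channels themselves
(via the factorial-moment flux calculus), so the same code covers
autoregulation, multi-gene motifs and arbitrary cooperativities: for gene
j the matched features are ``1{G_j = 0}`` and ``n_r 1{G_j = 1}`` with
``n_r`` the summed copy number of j's regulators.

A singular matching system falls back to the LMA values for that gene at
that instant (recorded as a flag); negative 4-HM parameters raise unless
clamping is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .linear_solver import DistributionOnCounts, ParamTrajectory, fsp_steady, fsp_transient
from .model import GeneNetwork, Reaction, ReactionSystem, compile_reactions
from .moments import (
    CachedMomentEvaluator,
    ConditionalMomentState,
    MomentBasis,
    MomentError,
    flux_terms,
    moment_matrix,
)

_DET_TOL = 1e-10
_G_TOL = 1e-9
#: matched rates beyond this magnitude are treated as matching degeneracies
_SIGMA_CAP = 1e5
#: ... or beyond this multiple of the LMA-rate scale for the same gene
_SIGMA_REL_CAP = 50.0
#: minimum gene-state occupancy for conditional moment-matching
_G_OCC = 1e-6

METHODS = ("lma", "hm2", "hm3", "hm4")


class MappingError(RuntimeError):
    pass


class NegativeParameterError(MappingError):
    """A matched effective rate came out negative (4-HM caveat)."""


@dataclass(frozen=True)
class LinearGeneParams:
    """Effective telegraph-model parameters for one gene.

    ``sigma_b`` is the effective off->on switching rate, ``sigma_u`` the
    on->off rate; ``rho0``/``rho1`` the per-state synthesis (burst)
    frequencies, ``d`` the degradation rate and ``p`` the geometric burst
    parameter.  LMA/2-HM leave synthesis and degradation unchanged;
    the 4-HM changes synthesis but not degradation; the 3-HM changes
    degradation.
    """

    gene: int
    sigma_b: float
    sigma_u: float
    rho0: float
    rho1: float
    d: float
    p: float = 0.0
    time: float | None = None
    method: str = "hm2"
    flags: tuple[str, ...] = ()

    def nonneg(self) -> "LinearGeneParams":
        if min(self.sigma_b, self.sigma_u, self.rho0, self.rho1, self.d) >= 0:
            return self
        clipped = {
            k: max(getattr(self, k), 0.0)
            for k in ("sigma_b", "sigma_u", "rho0", "rho1", "d")
        }
        return replace(self, flags=self.flags + ("clamped-negative",), **clipped)


class SampleEvaluator:
    """Moment evaluator backed by a matrix of sampled counts (N x S).

    Provides the same ``expect``/``eval_terms`` surface as
    :class:`~holimap.moments.ConditionalMomentState`, with expectations
    replaced by sample averages, plus direct propensity averages for
    channels (e.g. Michaelis-Menten) outside the polynomial calculus.
    """

    def __init__(self, counts: np.ndarray, system: ReactionSystem):
        self.counts = np.asarray(counts)
        self.system = system

    def _mask(self, cond) -> np.ndarray:
        m = np.ones(len(self.counts), dtype=bool)
        for j, state in cond:
            off, on = self.system.gene_state_pairs[j]
            m &= self.counts[:, on] == state
        return m

    def g_gene(self, j: int, state: int) -> float:
        return float(self._mask(((j, state),)).mean())

    def expect(self, orders, cond=()) -> float:
        vals = self._mask(cond).astype(float)
        for pos, order in dict(orders).items():
            col = self.counts[:, self.system.protein_of_gene[pos]].astype(float)
            for k in range(order):
                vals = vals * (col - k)
        return float(vals.mean())

    def eval_terms(self, terms) -> float:
        return float(sum(t.coef * self.expect(dict(t.orders), t.cond) for t in terms))

    def mean_propensity(self, rx: Reaction) -> float:
        return float(rx.propensity(self.counts).mean())

    def species_mean(self, s: int) -> float:
        return float(self.counts[:, s].mean())


# ---------------------------------------------------------------------------
# the matcher


def _switch_reactions(system: ReactionSystem, j: int) -> list[Reaction]:
    return [r for r in system.reactions if r.gene_flip and r.gene_flip[0] == j]


def _touches_protein(r: Reaction, prot: int) -> bool:
    if any(s == prot and dl != 0 for s, dl in r.stoich):
        return True
    return r.burst_species == prot


class Matcher:
    """Precompiled matching equations for a transcriptional network."""

    #: species whose conditional first moment forms the second matching
    #: feature: the target gene's own protein ("own") or the summed
    #: regulator copy numbers ("regulator"); identical for autoregulation
    match_feature = "own"

    def __init__(self, network: GeneNetwork, method: str):
        if method not in ("lma", "hm2", "hm4"):
            raise MappingError(f"matcher supports lma/hm2/hm4, got {method!r}")
        self.network = network
        self.method = method
        self.system = compile_reactions(network)
        M = network.n_genes
        self.regs = []
        for j in range(M):
            if self.match_feature == "own":
                self.regs.append([j])
                continue
            regs = sorted({e.regulator for e in network.regulators_of(j)})
            self.regs.append(regs if regs else [j])
        self.switch = [_switch_reactions(self.system, j) for j in range(M)]
        # nonlinear switching fluxes on the matched features
        self.b0 = [
            flux_terms(self.system, self.switch[j], ((j, 0),), {}) for j in range(M)
        ]
        self.b1 = []
        for j in range(M):
            terms = []
            for r in self.regs[j]:
                terms += flux_terms(self.system, self.switch[j], ((j, 1),), {r: 1})
            self.b1.append(terms)
        # stationarity complements: at steady state the switching flux of a
        # feature equals minus the flux of every other channel, which
        # involves only low-order moments and avoids the catastrophic
        # cancellation of the direct estimator (sample-moment route)
        def negate(terms):
            return [replace(t, coef=-t.coef) for t in terms]

        self.b0_st = []
        self.b1_st = []
        for j in range(M):
            other = [r for r in self.system.reactions if r not in self.switch[j]]
            self.b0_st.append(negate(flux_terms(self.system, other, ((j, 0),), {})))
            terms = []
            for r in self.regs[j]:
                terms += flux_terms(self.system, other, ((j, 1),), {r: 1})
            self.b1_st.append(negate(terms))
        if method == "hm4":
            prot = self.system.protein_of_gene
            self.r1, self.r2 = [], []
            for j in range(M):
                syn = [
                    r for r in self.system.reactions
                    if r.gene_flip is None and _touches_protein(r, prot[j])
                    and not (r.orders == ((prot[j], 1),) and r.stoich == ((prot[j], -1),))
                ]
                sw = [
                    r for r in self.system.reactions
                    if r.gene_flip is not None and _touches_protein(r, prot[j])
                ]
                subset = syn + sw
                self.r1.append(flux_terms(self.system, subset, (), {j: 1}))
                self.r2.append(flux_terms(self.system, subset, (), {j: 2}))
            # stationarity complements (the complement of the replaced set
            # is typically just the decay channel: perfectly conditioned)
            self.r1_st, self.r2_st = [], []
            for j in range(M):
                subset = set(id(r) for r in
                             [r for r in self.system.reactions
                              if _touches_protein(r, prot[j])
                              and not (r.orders == ((prot[j], 1),)
                                       and r.stoich == ((prot[j], -1),))])
                other = [r for r in self.system.reactions if id(r) not in subset]
                self.r1_st.append(negate(flux_terms(self.system, other, (), {j: 1})))
                self.r2_st.append(negate(flux_terms(self.system, other, (), {j: 2})))
        # per-channel pieces for the LMA (also the fallback path)
        self._lma_channels = []
        for j in range(M):
            chans = []
            for r in self.switch[j]:
                direction = "b" if r.gene_flip[2] == 1 else "u"
                orders = {}
                cond = []
                for s, h in r.orders:
                    hit = False
                    for jj, pair in enumerate(self.system.gene_state_pairs):
                        if s in pair:
                            cond.append((jj, pair.index(s)))
                            hit = True
                    if not hit:
                        orders[self.system.protein_of_gene.index(s)] = h
                chans.append((direction, r.rate, orders, tuple(cond)))
            self._lma_channels.append(chans)

    # -- parameter solvers -------------------------------------------------

    def lma_params(self, ev, strict: bool = True) -> list[LinearGeneParams]:
        out = []
        for j, g in enumerate(self.network.genes):
            sb = su = 0.0
            flags = ()
            for direction, rate, orders, cond in self._lma_channels[j]:
                if orders:
                    gp = ev.expect({}, cond)
                    if gp <= _G_TOL:
                        if strict:
                            raise MappingError(
                                f"gene {j}: unbound-state probability vanishes "
                                f"(g = {gp:.3e}); LMA conditional mean undefined"
                            )
                        flags = flags + ("vanishing-state-probability",)
                        gp = _G_TOL
                    eff = rate * ev.expect(orders, cond) / gp
                else:
                    eff = rate
                if direction == "b":
                    sb += eff
                else:
                    su += eff
            out.append(
                LinearGeneParams(j, sb, su, g.rho0, g.rho1, g.d, g.p,
                                 method="lma", flags=flags)
            )
        return out

    def _feature_moments(self, ev, j):
        g0, g1 = ev.expect({}, ((j, 0),)), ev.expect({}, ((j, 1),))
        m0 = sum(ev.expect({r: 1}, ((j, 0),)) for r in self.regs[j])
        m1 = sum(ev.expect({r: 1}, ((j, 1),)) for r in self.regs[j])
        return g0, g1, m0, m1

    def _solve_switch(self, ev, j, rhs1, rhs2, fallback):
        """Solve sigma_u~ g1 - sigma_b~ g0 = rhs1;
        sigma_u~ mu1 - sigma_b~ mu0 = rhs2.

        Degenerate systems — vanishing determinant, a practically
        unvisited gene state, or rate magnitudes outside any physical
        range — fall back to the LMA values for this gene.
        """
        g0, g1, m0, m1 = self._feature_moments(ev, j)
        det = -g1 * m0 + g0 * m1
        scale = max(abs(g1 * m0), abs(g0 * m1), 1e-30)
        ok = abs(det) > _DET_TOL * scale and min(g0, g1) > _G_OCC
        if ok:
            su = (-m0 * rhs1 + g0 * rhs2) / det
            sb = (-m1 * rhs1 + g1 * rhs2) / det
            if np.isfinite(su) and np.isfinite(sb):
                p = fallback(j)
                # rates far beyond the LMA (conditional-mean) scale signal
                # an ill-conditioned system, not physics
                cap = min(_SIGMA_CAP,
                          _SIGMA_REL_CAP * (p.sigma_b + p.sigma_u + 1e-9))
                if max(abs(su), abs(sb)) <= cap:
                    return sb, su, ()
                return p.sigma_b, p.sigma_u, p.flags + ("singular-matching",)
        p = fallback(j)
        return p.sigma_b, p.sigma_u, p.flags + ("singular-matching",)

    def hm2_params(self, ev, strict_lma: bool = False,
                   stationary: bool = False) -> list[LinearGeneParams]:
        """With ``stationary=True`` the matching fluxes are evaluated in
        their stationarity-complement form (exact at steady state and far
        better conditioned for sample moments)."""
        lma_cache: dict[int, LinearGeneParams] = {}

        def fallback(j):
            if j not in lma_cache:
                lma_cache[j] = self.lma_params(ev, strict=strict_lma)[j]
            return lma_cache[j]

        b0 = self.b0_st if stationary else self.b0
        b1 = self.b1_st if stationary else self.b1
        out = []
        for j, g in enumerate(self.network.genes):
            rhs1 = ev.eval_terms(b0[j])
            rhs2 = -ev.eval_terms(b1[j])
            sb, su, flags = self._solve_switch(ev, j, rhs1, rhs2, fallback)
            if min(sb, su) < 0:
                flags = flags + ("negative-switch-rate",)
            out.append(
                LinearGeneParams(j, sb, su, g.rho0, g.rho1, g.d, g.p,
                                 method="hm2", flags=flags)
            )
        return out

    def hm4_params(self, ev, clamp_negative: bool = False,
                   strict_lma: bool = False,
                   stationary: bool = False) -> list[LinearGeneParams]:
        network = self.network
        M = network.n_genes
        lma_cache: dict[int, LinearGeneParams] = {}

        def fallback(j):
            if j not in lma_cache:
                lma_cache[j] = self.lma_params(ev, strict=strict_lma)[j]
            return lma_cache[j]

        b0_t = self.b0_st if stationary else self.b0
        b1_t = self.b1_st if stationary else self.b1
        r1_t = self.r1_st if stationary else self.r1
        r2_t = self.r2_st if stationary else self.r2

        # stage 1: effective synthesis rates
        rho_bar = []
        for j, g in enumerate(network.genes):
            B = g.burst_size
            c2 = 2.0 * B * B if g.bursty else 0.0
            g0, g1 = ev.expect({}, ((j, 0),)), ev.expect({}, ((j, 1),))
            mu0, mu1 = ev.expect({j: 1}, ((j, 0),)), ev.expect({j: 1}, ((j, 1),))
            a = np.array([
                [B * g0, B * g1],
                [2 * B * mu0 + c2 * g0, 2 * B * mu1 + c2 * g1],
            ])
            rhs = np.array([ev.eval_terms(r1_t[j]), ev.eval_terms(r2_t[j])])
            det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
            scale = max(abs(a[0, 0] * a[1, 1]), abs(a[0, 1] * a[1, 0]), 1e-30)
            if abs(det) <= _DET_TOL * scale or min(g0, g1) <= _G_OCC:
                rho_bar.append((g.rho0, g.rho1, ("singular-matching",)))
            else:
                r0, r1 = np.linalg.solve(a, rhs)
                if np.isfinite(r0) and np.isfinite(r1) and max(abs(r0), abs(r1)) <= _SIGMA_CAP:
                    rho_bar.append((float(r0), float(r1), ()))
                else:
                    rho_bar.append((g.rho0, g.rho1, ("singular-matching",)))
        # stage 2: effective switching rates with synthesis correction
        out = []
        for j, g in enumerate(network.genes):
            rhs1 = ev.eval_terms(b0_t[j])
            corr = 0.0
            for r in self.regs[j]:
                gr = network.genes[r]
                Br = gr.burst_size
                for state, (rho, rbar) in enumerate(
                    zip((gr.rho0, gr.rho1), rho_bar[r][:2])
                ):
                    pjoint = ev.expect({}, ((j, 1), (r, state)))
                    corr += (rbar - rho) * Br * pjoint
            rhs2 = -ev.eval_terms(b1_t[j]) + corr
            sb, su, flags = self._solve_switch(ev, j, rhs1, rhs2, fallback)
            flags = flags + rho_bar[j][2]
            params = LinearGeneParams(j, sb, su, rho_bar[j][0], rho_bar[j][1],
                                      g.d, g.p, method="hm4", flags=flags)
            if min(sb, su, params.rho0, params.rho1) < 0:
                if not clamp_negative:
                    raise NegativeParameterError(
                        f"gene {j}: 4-HM produced a negative effective rate "
                        f"(sigma_b={sb:.3g}, sigma_u={su:.3g}, "
                        f"rho0={params.rho0:.3g}, rho1={params.rho1:.3g}); "
                        "pass clamp_negative=True to clip at zero"
                    )
                params = params.nonneg()
            out.append(params)
        return out

    def params(self, ev, **kw) -> list[LinearGeneParams]:
        return getattr(self, f"{self.method}_params")(ev, **kw)


# -- public one-shot wrappers ------------------------------------------------


def lma_params(moments: ConditionalMomentState, network: GeneNetwork) -> list[LinearGeneParams]:
    """Effective switch-on rates sigma_b_hat = sigma_b mu_{h,0} / g_0."""
    return Matcher(network, "lma").lma_params(moments, strict=True)


def hm2_params(moments, network: GeneNetwork) -> list[LinearGeneParams]:
    """Effective (sigma_u~, sigma_b~) from the 2-HM matching equations."""
    return Matcher(network, "hm2").hm2_params(moments)


def hm4_params(moments, network: GeneNetwork, clamp_negative: bool = False) -> list[LinearGeneParams]:
    """Effective (sigma_u-, sigma_b-, rho0-, rho1-) from the 4-HM equations."""
    return Matcher(network, "hm4").hm4_params(moments, clamp_negative=clamp_negative)


def hm3_params(samples, system: ReactionSystem) -> list[LinearGeneParams]:
    """3-HM effective parameters for post-regulation reaction systems.

    ``samples`` is a :class:`SampleEvaluator` (or an (N, S) count matrix).
    Gene switching is matched as in the 2-HM using numerically evaluated
    fluxes; every non-switching loss channel of each tracked species is
    folded into the effective decay rate ``d~``.
    """
    ev = samples if isinstance(samples, SampleEvaluator) else SampleEvaluator(samples, system)
    out = []
    for j, prot in enumerate(system.protein_of_gene):
        sw = _switch_reactions(system, j)
        sb, su, flags = _empirical_switch_match(ev, system, j, sw, prot)
        rho0 = rho1 = 0.0
        p = 0.0
        d = 0.0
        dtil_extra = 0.0
        mean_n = ev.species_mean(prot)
        for r in system.reactions:
            if r.gene_flip is not None:
                continue
            produces = r.burst_species == prot or any(
                s == prot and dl > 0 for s, dl in r.stoich
            )
            if produces:
                state = _required_state(system, r, j)
                rate = r.rate
                if r.burst_species == prot:
                    p = r.burst_p
                if state in (None, 0):
                    rho0 += rate
                if state in (None, 1):
                    rho1 += rate
                continue
            loss = -sum(dl for s, dl in r.stoich if s == prot)
            if loss <= 0:
                continue
            if r.orders == ((prot, 1),) and r.mm is None and len(r.stoich) == 1:
                d += r.rate  # the plain first-order decay channel
            else:
                flux = ev.mean_propensity(r) * loss
                if flux == 0.0:
                    continue
                if mean_n <= _G_TOL:
                    raise MappingError(
                        f"mean count of tracked species "
                        f"{system.species[prot]!r} vanishes; 3-HM loss "
                        "matching undefined"
                    )
                dtil_extra += flux / mean_n
        out.append(
            LinearGeneParams(j, sb, su, rho0, rho1, d + dtil_extra, p,
                             method="hm3", flags=flags)
        )
    return out


def _required_state(system: ReactionSystem, r: Reaction, j: int):
    off, on = system.gene_state_pairs[j]
    for s, _h in r.orders:
        if s == off:
            return 0
        if s == on:
            return 1
    return None


def _empirical_switch_match(ev: SampleEvaluator, system: ReactionSystem, j: int,
                            switch, prot: int):
    """2-HM switch matching with sample-average fluxes (handles any
    propensity form, including Michaelis-Menten channels)."""
    counts = ev.counts.astype(float)
    off, on = system.gene_state_pairs[j]
    # regulator species: those whose counts enter j's switching propensities
    regs = sorted(
        {s for r in switch for s, _h in r.orders if s not in (off, on)}
    ) or [prot]
    ind0 = counts[:, off]
    ind1 = counts[:, on]
    nreg = counts[:, regs].sum(axis=1)
    flux1 = flux2 = 0.0
    for r in switch:
        a = r.propensity(ev.counts)
        post = counts.copy()
        for s, dl in r.stoich:
            post[:, s] += dl
        flux1 += float((a * (post[:, off] - ind0)).mean())
        nreg_post = post[:, regs].sum(axis=1)
        flux2 += float((a * (nreg_post * post[:, on] - nreg * ind1)).mean())
    g0, g1 = float(ind0.mean()), float(ind1.mean())
    m0, m1 = float((nreg * ind0).mean()), float((nreg * ind1).mean())
    det = -g1 * m0 + g0 * m1
    scale = max(abs(g1 * m0), abs(g0 * m1), 1e-30)
    rhs1, rhs2 = flux1, -flux2
    if abs(det) <= _DET_TOL * scale:
        # LMA-style fallback: conditional-mean propensities
        sb = su = 0.0
        for r in switch:
            a = r.propensity(ev.counts)
            to_on = r.gene_flip[2] == 1
            gp = max(g0 if to_on else g1, _G_TOL)
            eff = float(a.mean()) / gp
            if to_on:
                sb += eff
            else:
                su += eff
        return sb, su, ("singular-matching",)
    su = (-m0 * rhs1 + g0 * rhs2) / det
    sb = (-m1 * rhs1 + g1 * rhs2) / det
    return float(sb), float(su), ()


# ---------------------------------------------------------------------------
# the self-consistent closure solve


@dataclass
class HolimapSolution:
    method: str
    mode: str
    t_grid: np.ndarray | None
    params: list  # per gene: LinearGeneParams (steady) or ParamTrajectory
    distributions: list  # per gene: DistributionOnCounts or list per time
    moments: list[ConditionalMomentState] | ConditionalMomentState
    flags: list = field(default_factory=list)


class _Closure:
    """Closed moment ODE: the linear-network RHS with matching-determined
    rates re-evaluated at every right-hand-side call."""

    def __init__(self, network: GeneNetwork, method: str):
        self.network = network
        self.method = method
        h = network.max_cooperativity
        K = h if method == "lma" else h + 1
        self.matcher = Matcher(network, method)
        system = self.matcher.system
        M = network.n_genes
        self.basis = MomentBasis(M, K, K + h)
        nm = self.basis.n_main

        def mat(reactions):
            a = moment_matrix(system, self.basis, reactions)
            if a[:, nm:].nnz:
                raise MomentError("linear component unexpectedly unclosed")
            return a[:, :nm].toarray() if nm <= 400 else a[:, :nm]

        base = []
        self.syn_comps = []
        prot0 = 2 * M
        for r in system.reactions:
            if r.gene_flip is not None:
                continue
            is_syn = r.burst_species >= 0 or any(dl > 0 for _s, dl in r.stoich)
            if method == "hm4" and is_syn:
                continue
            base.append(r)
        self.A_base = mat(base)
        self.A_on, self.A_off = [], []
        for j in range(M):
            off, on = 2 * j, 2 * j + 1
            r_on = Reaction("on", 1.0, ((off, 1),), ((off, -1), (on, 1)),
                            gene_flip=(j, 0, 1))
            r_off = Reaction("off", 1.0, ((on, 1),), ((off, 1), (on, -1)),
                             gene_flip=(j, 1, 0))
            self.A_on.append(mat([r_on]))
            self.A_off.append(mat([r_off]))
        if method == "hm4":
            self.A_syn = []
            for j, g in enumerate(network.genes):
                comps = []
                for state in (0, 1):
                    idx = 2 * j + state
                    if g.bursty:
                        r = Reaction("syn", 1.0, ((idx, 1),), (),
                                     burst_species=prot0 + j, burst_p=g.p)
                    else:
                        r = Reaction("syn", 1.0, ((idx, 1),), ((prot0 + j, 1),))
                    comps.append(mat([r]))
                self.A_syn.append(comps)
        self.flags: set = set()
        self._row_cache: dict = {}

    def evaluator(self, vec: np.ndarray) -> CachedMomentEvaluator:
        return CachedMomentEvaluator(self.basis, vec, self._row_cache)

    def params_of(self, vec: np.ndarray, clamp_negative: bool = True):
        state = self.evaluator(vec)
        if self.method == "lma":
            ps = self.matcher.lma_params(state, strict=False)
        elif self.method == "hm2":
            ps = self.matcher.hm2_params(state)
        else:
            ps = self.matcher.hm4_params(state, clamp_negative=clamp_negative)
        for p in ps:
            self.flags.update(p.flags)
        return ps

    def rhs(self, vec: np.ndarray, params=None) -> np.ndarray:
        ps = self.params_of(vec) if params is None else params
        out = self.A_base @ vec
        for j, p in enumerate(ps):
            out = out + p.sigma_b * (self.A_on[j] @ vec)
            out = out + p.sigma_u * (self.A_off[j] @ vec)
            if self.method == "hm4":
                out = out + p.rho0 * (self.A_syn[j][0] @ vec)
                out = out + p.rho1 * (self.A_syn[j][1] @ vec)
        return out

    def assemble(self, params) -> np.ndarray:
        """Dense closure matrix at frozen effective parameters."""
        a = np.asarray(self.A_base, dtype=float).copy()
        for j, p in enumerate(params):
            a += max(p.sigma_b, 0.0) * np.asarray(self.A_on[j])
            a += max(p.sigma_u, 0.0) * np.asarray(self.A_off[j])
            if self.method == "hm4":
                a += max(p.rho0, 0.0) * np.asarray(self.A_syn[j][0])
                a += max(p.rho1, 0.0) * np.asarray(self.A_syn[j][1])
        return a

    def rhs_physical(self, vec: np.ndarray) -> np.ndarray:
        """Closure RHS with the physical (fallback/clamped) parameter map —
        the map the steady-state solvers are a fixed point of."""
        ps = [p.nonneg() for p in _physical_params(self, vec)]
        return self.rhs(vec, params=ps)


def _integrate_closure(cl: _Closure, vec0, t_grid, rtol=1e-8, atol=1e-10):
    t_grid = np.asarray(t_grid, dtype=float)
    # integrate the physical (fallback/clamped) closure; the
    # frozen-parameter matrix is an accurate, cheap Jacobian proxy
    jac = lambda _t, v: cl.assemble(_physical_params(cl, v))
    sol = solve_ivp(lambda _t, v: cl.rhs_physical(v), (t_grid[0], t_grid[-1]), vec0,
                    t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol, jac=jac)
    if not sol.success or not np.isfinite(sol.y).all():
        t_bad = sol.t[-1] if len(sol.t) else t_grid[0]
        raise MappingError(
            f"closed {cl.method} moment integration failed near t = {t_bad:g}: "
            f"{sol.message}"
        )
    return sol


def _linear_steady(cl: _Closure, params) -> np.ndarray:
    """Steady state of the linear moment system at fixed effective rates.

    The redundant zeroth-order equation for joint state 0 is replaced by
    the normalization constraint sum_s g_s = 1 (the zero-order moments
    occupy the first 2^M positions of the basis)."""
    a = cl.assemble(params)
    ns = cl.basis.n_states
    a[0, :] = 0.0
    a[0, :ns] = 1.0
    b = np.zeros(cl.basis.n_main)
    b[0] = 1.0
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise MappingError(f"singular linear moment system: {exc}") from exc


def _physical_params(cl: _Closure, vec):
    """Matched parameters with unphysical (negative-rate) genes replaced
    by their LMA values — keeps fixed-point iterates inside the physical
    parameter region while transients settle."""
    state = cl.evaluator(vec)
    ps = cl.params_of(vec, clamp_negative=True)
    out = []
    hm2 = lma = None
    for j, p in enumerate(ps):
        if max(p.sigma_b, 0.0) > 0.0 or max(p.sigma_u, 0.0) > 0.0:
            out.append(p)
            continue
        # a fully collapsed switch pair: degrade gracefully hm4 -> hm2 -> lma
        q = None
        if cl.method == "hm4":
            if hm2 is None:
                hm2 = cl.matcher.hm2_params(state)
            if max(hm2[j].sigma_b, 0.0) > 0.0 or max(hm2[j].sigma_u, 0.0) > 0.0:
                q, tag = hm2[j], "hm2-fallback"
        if q is None:
            if lma is None:
                lma = cl.matcher.lma_params(state, strict=False)
            q, tag = lma[j], "lma-fallback"
        out.append(replace(p, sigma_b=max(q.sigma_b, 0.0),
                           sigma_u=max(q.sigma_u, 0.0),
                           rho0=cl.network.genes[j].rho0,
                           rho1=cl.network.genes[j].rho1,
                           flags=p.flags + (tag,)))
    return out


def _fixed_point(cl: _Closure, vec0, tol, max_iter=300, damping=0.5):
    vec = vec0.copy()
    prev = np.inf
    best, best_resid = vec, np.inf
    for it in range(max_iter):
        try:
            new = _linear_steady(cl, _physical_params(cl, vec))
        except MappingError:
            break
        vec = damping * new + (1.0 - damping) * vec if it else new
        resid = np.max(np.abs(cl.rhs_physical(vec))) / max(1.0, np.max(np.abs(vec)))
        if resid < best_resid:
            best, best_resid = vec, resid
        if resid < tol:
            return vec, resid
        if resid > 1.2 * prev:
            damping = max(0.5 * damping, 0.02)
        prev = resid
    return best, best_resid


def _newton_polish(cl: _Closure, vec, tol):
    """Refine a near-steady moment vector by root finding on the closure
    RHS with the redundant equation replaced by the normalization."""
    from scipy.optimize import root

    ns = cl.basis.n_states

    def func(v):
        g = cl.rhs_physical(v).copy()
        g[0] = v[:ns].sum() - 1.0
        return g

    try:
        sol = root(func, vec, method="hybr")
    except MappingError:
        return vec, np.inf
    if not np.isfinite(sol.x).all():
        return vec, np.inf
    resid = np.max(np.abs(cl.rhs_physical(sol.x))) / max(1.0, np.max(np.abs(sol.x)))
    return sol.x, resid


def _steady_closure(cl: _Closure, tol=1e-8, init_counts=None):
    """Self-consistent steady state of the closed moment system.

    A damped fixed-point iteration (exact linear-network steady solves
    alternating with re-matching, from the zero-protein initial
    condition) locates the physical basin; a Newton root solve on the
    closure RHS then polishes to the residual tolerance.  The 4-HM,
    which can cycle in strongly bistable regimes, is preconditioned with
    the 2-HM solution when needed."""
    vec0 = ConditionalMomentState.initial(cl.basis, counts=init_counts).vec
    vec, resid = _fixed_point(cl, vec0, tol)
    if resid < tol:
        return vec
    vec2, resid2 = _newton_polish(cl, vec, tol)
    if resid2 < tol:
        return vec2
    if cl.method == "hm4":
        pre = _Closure(cl.network, "hm2")
        vpre, rpre = _fixed_point(pre, vec0, tol)
        if rpre >= tol:
            vpre, rpre = _newton_polish(pre, vpre, tol)
        vec3, resid3 = _fixed_point(cl, vpre, tol, max_iter=150, damping=0.2)
        if resid3 < tol:
            return vec3
        vec4, resid4 = _newton_polish(cl, vec3, tol)
        if resid4 < tol:
            return vec4
        resid = min(resid, resid2, resid3, resid4)
    else:
        resid = min(resid, resid2)
    raise MappingError(
        f"closure steady state not reached (best residual {resid:.2e} > {tol})"
    )


def holimap_solve(network: GeneNetwork, method: str = None, mode: str = "steady",
                  t_grid=None, tol: float = 1e-8, fsp_tol: float = 1e-8,
                  clamp_negative: bool = True, init_counts=None):
    """Solve a nonlinear gene network by its linear-mapping approximation.

    Closes the conditional moment equations with the chosen matching
    (evaluated at every RHS call), integrates them (or drives them to
    steady state), and computes each gene's protein distribution from the
    decoupled effective telegraph model by FSP.  The default method is
    the 4-HM in steady state and the 2-HM for transients (the 4-HM can be
    numerically unstable at short times).
    """
    if method is None:
        method = "hm4" if mode == "steady" else "hm2"
    method = method.lower()
    if method == "hm3":
        raise MappingError(
            "the 3-HM applies to post-regulation reaction systems and is "
            "driven by sample moments; use hybrid_solve(..., method='hm3')"
        )
    if method not in ("lma", "hm2", "hm4"):
        raise MappingError(f"unknown method {method!r}")
    cl = _Closure(network, method)
    if mode == "steady":
        vec = _steady_closure(cl, tol=tol, init_counts=init_counts)
        if clamp_negative:
            params = [p.nonneg() for p in _physical_params(cl, vec)]
        else:
            params = cl.params_of(vec, clamp_negative=False)
        dists = [fsp_steady(p.nonneg(), tol=fsp_tol) for p in params]
        return HolimapSolution(method, mode, None, params, dists,
                               ConditionalMomentState(cl.basis, vec),
                               flags=sorted(cl.flags))
    if mode != "transient":
        raise MappingError(f"unknown mode {mode!r}")
    if t_grid is None:
        raise MappingError("transient mode requires t_grid")
    t_grid = np.asarray(t_grid, dtype=float)
    sol = _integrate_closure(
        cl, ConditionalMomentState.initial(cl.basis, counts=init_counts).vec, t_grid)
    moments = [ConditionalMomentState(cl.basis, sol.y[:, k], float(t))
               for k, t in enumerate(t_grid)]
    per_time = [[p.nonneg() for p in _physical_params(cl, m.vec)] for m in moments]
    trajectories, dists = [], []
    for j, g in enumerate(network.genes):
        tr = ParamTrajectory(
            times=t_grid,
            sigma_b=np.array([max(pt[j].sigma_b, 0.0) for pt in per_time]),
            sigma_u=np.array([max(pt[j].sigma_u, 0.0) for pt in per_time]),
            rho0=np.array([max(pt[j].rho0, 0.0) for pt in per_time]),
            rho1=np.array([max(pt[j].rho1, 0.0) for pt in per_time]),
            d=g.d, p=g.p,
        )
        trajectories.append(tr)
        init_j = None
        if init_counts is not None and init_counts[j] > 0:
            init_j = np.zeros((2, int(init_counts[j]) + 1))
            init_j[0, int(init_counts[j])] = 1.0
        dists.append(fsp_transient(tr, init_j, t_grid, tol=fsp_tol))
    return HolimapSolution(method, mode, t_grid, trajectories, dists, moments,
                           flags=sorted(cl.flags))
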