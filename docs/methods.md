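# Methods

## The model class

A transcriptional network has `M` genes, each switching between an
inactive state `G_j` and an active state `G_j*`. Gene `j` synthesises its
protein `P_j` at burst frequency `rho_j^0` (inactive) or `rho_j^1`
(active); each synthesis event produces a geometric number of molecules,
`P(k = n) = p_j^n (1 - p_j)`, with mean burst size `B_j = p_j/(1 - p_j)`
(`p_j = 0` is the non-bursty, one-molecule-per-event limit). Proteins
decay at rate `d_j`. Regulation enters through cooperative protein-gene
binding with the combinatorial propensity

    sigma * n (n-1) ... (n-h+1),

`h` being the number of regulator copies bound per event. Two
conventions are compiled: reversible motif binding `G + hP <=> G*`
(binding sequesters the `h` molecules, unbinding releases them — used by
the autoregulatory loop and the two-/three-node motifs) and irreversible
regulation events that consume the regulator (the randomly connected
network model, where genes also switch spontaneously at rates
`alpha_j^0`, `alpha_j^1`).

Post-translational/post-transcriptional systems (protein sequestration,
two-step Michaelis-Menten phosphorylation, enzymatic mRNA degradation,
microRNA-mRNA complexes) are expressed directly as reaction systems over
species counts; their rate constants are package placeholders with
molecule numbers of order tens, exposed as keyword arguments.

## Conditional moment calculus

For each joint gene-state vector `s` the state of the moment system is
the probability `g_s` and the conditional factorial moments
`mu_{m,s} = E[prod_j (n_j)_{m_j} ; G = s]`, capped at total order
`K = h_max + 1` (the order the matching consumes). Evolution equations
are generated directly from the reaction channels: each channel with
propensity `a(x)` and jump `x -> x'` contributes `E[a(x)(f(x') - f(x))]`
to `d E[f]/dt`, and for falling-factorial propensities this expands
exactly into factorial moments (geometric jumps use
`E[(k)_r] = r! B^r`). The expansion is validated term-by-term against
the hand-written autoregulation equations and, on random probability
vectors, against a brute-force truncated-CME generator (deviation below
1e-6 is asserted; the comparison is exact up to float accumulation
because the probe vectors are supported away from the truncation
boundary).

The conditional basis is exponential in `M`; the builder refuses
`M > 12` and the hybrid route (below) is the intended tool for larger
networks.

## The mapping hierarchy

Every protein-dependent switching reaction of gene `j` is replaced by a
first-order gene switch. The effective rates come from moment-matching:

* **LMA** — each binding channel's propensity is replaced by its
  conditional mean: `sigma_b_hat = sigma_b E[(n)_h ; G_j=0] / g_0`;
  unbinding and spontaneous rates are unchanged.
* **2-HM** — `(sigma_u~, sigma_b~)` solve the 2x2 system obtained by
  matching the gene-state equation and the bound-state first-moment
  equation of the target's own protein (`n_j 1{G_j=1}`). For
  autoregulation this is exactly the printed matching system; for
  multi-gene networks the own-protein feature is the package's choice —
  the alternative (the regulator's conditional moment) degenerates at
  any steady state of the decoupled linear network because cross-gene
  moments factorize there.
* **4-HM** — additionally replaces the synthesis rates: `(rho0-, rho1-)`
  are matched first through the unconditional first- and second-moment
  equations (which absorb the protein flux of the replaced binding
  reactions), then the switch rates through the 2-HM equations with the
  synthesis-difference correction term.
* **3-HM** (post-regulation systems) — switch rates as in the 2-HM with
  numerically evaluated fluxes (this handles Michaelis-Menten channels),
  plus an effective decay `d~ = d + sum_r E[a_r] loss_r / E[n]` folding
  every bimolecular/enzymatic loss channel of the tracked species into
  first-order decay. The 3-HM is driven by SSA sample moments only.

Degenerate matching systems (vanishing determinant, a gene state with
occupancy below 1e-6, non-finite or absurdly large solutions — above
1e5, or 50x the LMA scale for the same gene) fall back to the LMA values
for that gene at that instant and are flagged; a fully collapsed 4-HM
pair degrades to the 2-HM first. Negative 4-HM parameters raise by
default (`clamp_negative` clips and flags instead) — the method is known
to leave the physical region when binding and unbinding rates are large.

## Solving the closed system

**Steady state.** The closure is a fixed-point problem: moments
determine effective rates; the linear moment system at those rates has
an exactly solvable steady state (one redundant equation swapped for
normalization). A damped iteration from the zero-protein initial
condition locates the physical basin and a Newton solve on the closure
residual polishes it to an infinity-norm residual below 1e-8 (relative
to the moment scale). The 4-HM, which can cycle in strongly bistable
regimes, is preconditioned with the 2-HM solution when the direct
iteration stalls. Long-time integration of the closed ODE was abandoned
as the primary route: the 4-HM closure is numerically unstable at short
times and the piecewise fallback dynamics defeat stiff integrators.

Deterministic closures have an intrinsic limitation in strongly
bistable/bimodal regimes: the self-consistent moment solution commits to
one basin and loses the mixture, and for multi-gene networks the
decoupled linear system cannot retain the cross-gene correlations behind
type-III bimodality at all (the correct mixture moments are a fixed
point of the closure map, but an unstable one). Sample moments from the
SSA do carry this information, which is why the hybrid route is the
recommended method beyond one gene.

**Transients.** The matching is evaluated inside the ODE right-hand
side (no outer iteration), integrated with LSODA using the
frozen-parameter matrix as the Jacobian proxy; effective-rate
trajectories are recorded on the output grid and the decoupled per-gene
telegraph models are then solved by FSP with piecewise-linear rate
interpolation.

## FSP

Truncated generators are assembled by direct state enumeration; a
geometric burst channel contributes jump weights `p^k (1-p)` truncated
at a 1e-12 tail. Outflow past the truncation is discarded, so
`1 - sum(p)` bounds the error; truncations start at
`max(64, mean + 10 sd)` and double until the tail criterion (1e-8 by
default) holds. Stationary vectors pin a reference state found by crude
forward-Euler smoothing and solve the sparsity-preserving reduced system
with the `MMD_AT_PLUS_A` ordering; the residual is always verified and a
dense-normalization-row solve is the fallback (SuperLU can fail silently
when the reference state carries negligible mass in metastable systems).
Direct nonlinear FSP is the ground-truth oracle for one- and two-gene
networks (state-space cap 2e6).

## SSA and the hybrid method

The SSA is the direct (Gillespie) method with numba-compiled inner
loops, per-trajectory RNG streams derived from `(seed, index)`, exact
recording at grid times, and geometric burst draws by inverse CDF.

The hybrid solve estimates conditional sample moments at every output
time, substitutes them into the matching equations, and solves each
gene's effective telegraph model by FSP. Missing data are handled
conservatively: a gene state never visited at some time keeps the last
valid parameters (LMA with unconditional moments before any exist). No
smoothing is applied to the sample-moment series. Steady-state hybrid
solves pool the last 20% of the recording window (long-run time
averaging — for stationary moments a few hundred long trajectories are
much cheaper than a huge ensemble).

Steady-state matching additionally uses the *stationarity-complement*
form of the flux estimators: at stationarity the switching flux of each
matched feature equals minus the total flux of every other channel,
which involves only low-order moments. The direct estimator subtracts
two large nearly-cancelling binding/unbinding terms and its variance is
amplified by the square of the cancellation ratio (easily 1e3-1e4);
the complement form is exact at stationarity and converges with a few
hundred long-run trajectories. Transient matching necessarily keeps the
direct fluxes.

The sample-size sufficiency check runs the full hybrid solve at `N` and
`3N` trajectories and requires their time-averaged Hellinger distance to
fall below 0.02: enlarging the ensemble would then not change the
answer materially. Note this compares the *hybrid outputs*; raw
histograms over a few hundred bins can never be 0.02-close at
`N = 2000`.

## Diagnostics

The accuracy metric is the Hellinger distance
`HD = sqrt(1 - sum sqrt(p q))` (bounded in [0,1]; the `L2/sqrt(2)`
convention is deliberately rejected). Modes are local maxima with
prominence above 1e-4 by default (suppresses truncation ripple; the
boundary `n = 0` may be a mode, plateaus merge). Mean-field rate
equations replace falling factorials by powers and geometric bursts by
their mean; classification enumerates fixed points by multi-start
hybrid-Powell root finding with numerical Jacobians — two or more stable
roots is bistable, no stable root with a sustained long-horizon
oscillation is oscillatory.

## Standard study conditions

Chosen once (figure-level parameter values are not printed in the main
text) and used by the tests and the acceptance script:

* **Accuracy battery** (autoregulation, steady state): `rho_u = 5`,
  `rho_b = 50`, `B = 1` (`p = 0.5`), `d = 1`; `sigma_u/d` log-spaced in
  [1, 10] — the fast-switching regime measured for most genes;
  `sigma_b` at 0.02–0.5 multiples of the per-`(sigma_u, h)` binding
  transition (the rate at which the bound-state probability crosses
  1/2, located by bisection on the nonlinear FSP). Cooperative
  propensities scale with the h-th factorial moment of the regulator,
  so absolute binding-rate ranges are not comparable across `h`; the
  transition-relative grid is. 15x15 grids in the acceptance test, 8x8
  in the acceptance script.
* **Repressilator**: `rho_u = 150`, `rho_b = 0`, `d = 1`,
  `sigma_u = 1`, `sigma_b = 8e-6` (repression threshold
  `(sigma_u/sigma_b)^{1/3} = 50`), `h = 3` (deterministic oscillation;
  none for `h <= 2`), initial condition `P = (90, 0, 0)` — a symmetric
  start would cancel the ensemble oscillation by phase averaging. The
  hybrid comparison uses `N = 2000` against a 1e5-trajectory reference
  over `t in [0, 21]`. Large copy numbers are the regime where the
  hybrid's advantage exists at all: raw 2000-trajectory histograms over
  a ~250-bin support have a noise floor above 0.1, while the smooth
  hybrid reconstruction errs at ~0.1 or less; at tens of molecules the
  histogram floor (~0.06) undercuts any closure's reconstruction error.
* **Two-node negative feedback** (type-III bimodality): `sigma_u = 100`
  for both genes (everything switches much faster than decay), `h = 1`,
  repressed gene `rho_u1 = 40, rho_b1 = 1`, activator-driven repressor
  gene `rho_u2 = 0.2, rho_b2 = 40`. Bimodality appears at strong
  repressor binding (`sigma_b1 ~ 300`, per-molecule rebinding dominates
  unbinding) and weak activation (`sigma_b2 <~ 1e-2`): the low-copy
  repressor is a slow hidden switch even though every gene-state
  transition is fast. Binding rates are indexed by the target gene.
* **Toggle switch**: `sigma_b = 0.3`, `sigma_u = 50`, `rho_u = 40`,
  `rho_b = 1`, `h = 2`: deterministically bistable; the bistable
  parameter region is strictly inside the stochastically bimodal one.

## What the synthetic conditions do and do not show

All inputs are generated from the in-text models; there are no external
data. Passing tests demonstrate the mathematical fidelity of the
pipeline (moment derivation, matching algebra, FSP and SSA exactness)
and the method phenomenology (accuracy ordering, bimodality criteria,
hybrid behaviour) under the documented conditions. They do not
establish accuracy for real gene-expression data, for promoters with
more than two states, for cell-division/partitioning noise, or for
parameter regimes far from those above — in particular, deep slow-
switching bistability defeats any deterministic moment closure (the
mixture solution exists but is not selectable without sample
information), and at high cooperativity the matching system becomes
ill-conditioned when the two gene states have nearly equal conditional
means, inflating the sample sizes the hybrid needs.

## Numerical choices

* Moment/closure steady residual: inf-norm < 1e-8 relative; integrator
  tolerances rtol 1e-8 / atol 1e-10 (1e-10/1e-12 inside steady-state
  homing); FSP truncation deficit 1e-8.
* Matching degeneracy thresholds: determinant below 1e-10 relative,
  state occupancy below 1e-6, rate magnitude above 1e5 or 50x the LMA
  scale.
* Mode prominence 1e-4 (1e-3 in sweeps of coarse two-gene truncations).
* The acceptance script runs 8x8 battery grids and a 3e4-trajectory
  reference ensemble; the acceptance tests use the full 15x15 grids and
  the 1e5-trajectory reference.
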