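# Methods

`rxnflow` builds random chemical reaction networks whose substrate graphs
follow four complex-network models, equips them with thermodynamically
consistent mass-action kinetics, drives them out of equilibrium by clamping
two species, and measures how flow and dissipation distribute over the
network. This note records the model assumptions, the parameters that
matter, the numerical choices, and the places where the design was
genuinely open.

## Reaction networks

A network is a set of `N` species and `M` reversible reactions, each either
1↔1 (`X ⇌ Y`, "linear") or 2↔2 (`X + Z ⇌ Y + W`, "nonlinear"). Left and
right stoichiometric matrices `L`, `R` (non-negative integers; duplicated
species accumulate, so `A + A ⇌ …` has a coefficient of 2) give the
stoichiometric matrix `N = R − L` and the kinetics

    dx/dt = N · v(x),   v_j = v_j⁺ − v_j⁻,
    v_j⁺ = k_j^f Π_i x_i^{L_ij},   v_j⁻ = k_j^b Π_i x_i^{R_ij}.

Because both reaction types conserve molecule count, every column of `N`
sums to zero and closed networks conserve total concentration. No element
or mass balance beyond this is imposed: species are abstract, which keeps
almost every pair of species connected by transformation pathways — the
regime the study needs.

The *substrate graph* joins two species whenever some reaction has them on
opposite sides: one edge per linear reaction, the four cross pairs
(`A–B, A–D, C–B, C–D` for `A + C ⇌ B + D`) per nonlinear one, with
multiplicity. The *directed* substrate graph orients each reaction's edges
along its net flow (reactant→product for positive net rate), so the directed
topology changes with the boundary conditions even though the reaction list
does not.

## Graph generators

All four generators return exactly `M` directed edges over `N` nodes,
allowing self-loops and parallel edges; orientation is uniform per edge
(the models are undirected, reactions need a direction, and a random
orientation reproduces the nonzero antiparallel-pair baselines that a
growth-ordered orientation could not).

* **ER** — both endpoints of every edge uniform. Self-loop count has mean
  `M/N`.
* **BA** — growth with preferential attachment, `m = round(M/N)` edges per
  entering node; the seed core is a path over the first `m` nodes, and the
  entering node sits in its own attachment pool with a phantom degree of 1,
  which is what permits self-loops. The edge count is padded/trimmed to
  exactly `M` with uniformly chosen preferential edges. The guards on this
  under-specified mechanism are the scale-free degree tail (preserved under
  coupling) and the observed self-loop counts, not the micro-rule.
* **WS** — ring lattice with `k = 2M/N` neighbours (must be even), then a
  fraction `α = 0.1` of edges has one uniformly chosen endpoint re-sampled
  uniformly (self-loops possible). Node ids are ring positions; at `α = 0`
  the average local clustering equals the lattice closed form
  `3(k−2)/(4(k−1))`.
* **PS** — hierarchically modular: nodes are distributed round-robin over
  `2^h` elementary modules (sizes differ by at most one) forming the leaves
  of a binary tree of height `h = 8`; an unordered pair `{u, v}` (`u = v`
  allowed) is drawn with weight `p^l`, `l` the lowest tree level at which
  the two nodes share a module, `p = 0.5`. Sampling is exact two-stage
  (level by total weight, then a uniform pair at that level), not rejection.

## Coupling linear reactions into nonlinear ones

Nonlinear networks start from a linear network of `M = 3000` reactions;
`C = 1000` sequential draws pick a pair of distinct unused linear reactions
with probability proportional to a model-specific weight and replace
`A ⇌ B`, `C ⇌ D` by `A + C ⇌ B + D`. The weight preserves the model
signature through the two *new* substrate edges `A–D` and `C–B`:

| model | weight |
|---|---|
| ER | 1 (uniform pairs) |
| BA | deg(B)·deg(D) in the substrate graph *at draw time* |
| WS | 1 if both new edges span ring distance ≤ k/2, else 0 |
| PS | `p^{l(A,D)} · p^{l(C,B)}` |

Reactions sharing a species may couple; `A ⇌ B` with `B ⇌ C` yields
`A + B ⇌ B + C` and a substrate self-edge at `B`. For ER the law reduces to
a uniform random matching; for BA the weight factorizes, so the first
reaction is drawn from its exact marginal and the partner from the
conditional; for WS/PS the joint weight does not factorize and the draws
use an explicit M×M weight table updated after every removal — the same
sequential law, computed exactly. Degenerate inputs raise a
coupling-infeasible error naming the model (pool exhausted, or all weights
zero, e.g. a WS pool whose every pairing would need a far edge).

## Thermodynamic parametrization

Units: `k_B = T = 1`. Formation energies `μ⁰_i ~ N(0, 1)`. Every reaction
draws one activation energy from the Planck-like density

    P(x) = (6/π²) / (x³ (e^{1/x} − 1)),   x > 0,

which decays super-polynomially near zero (an effective lower bound on
barriers) and like `(6/π²) x⁻²` for large `x` — so it has no finite mean
and, with `k = e^{−E_a}`, occasionally (≈1.6·10⁻⁴ of draws) produces a
barrier beyond ~700 whose rate constant underflows to an exactly frozen
reaction; the analysis layer treats those as zero-dissipation. Sampling is
exact: substituting `u = 1/x` gives the Bose–Einstein-like density
`(6/π²) u/(e^u − 1) = Σ_n (6/π²) n⁻² · Gamma(2, 1/n)`, so a draw is
`1/Gamma(2, 1/n)` with `n ~ Zipf(2)`. The test suite cross-checks this
against a quadrature CDF with a Kolmogorov–Smirnov test.

The sampled barrier is assigned to the **exergonic** direction (products
with lower total `μ⁰`); the opposite direction gets `E_a + |Δμ⁰_j|`,
`Δμ⁰_j = Σ_i N_ij μ⁰_i`. With Arrhenius prefactor 1 this enforces detailed
balance, `k^f/k^b = e^{−Δμ⁰}`, and closed networks relax to Boltzmann
states `x_i ∝ e^{−μ⁰_i}` (one constant per connected component) with
balanced one-way rates. An alternative `direction_rule="literal_text"`
swaps the assignment (sampled barrier on the endergonic side); it violates
the equilibrium balance and exists only for sensitivity analysis — all
validation runs use the detailed-balance rule.

Before each simulation the two boundary species' `μ⁰` are set to zero and
all energetics recomputed (`rezero_boundary`, idempotent); the re-zeroing
re-identifies the exergonic direction per reaction, since the rates are
explicitly recalculated. This makes the boundary chemical potentials plain
`ln c` and the whole network equivalent, at steady state, to one effective
reaction `b1 ⇌ b2` with equal rate coefficients, giving the balance

    σ_tot = v · ln(c1/c2)

used as a global consistency check on every run.

## Entropy production

Per reaction, at any state with strictly positive one-way rates,

    σ_j = (v_j⁺ − v_j⁻) · ln(v_j⁺ / v_j⁻) ≥ 0,

zero exactly at detailed balance. The equivalent potential form is the
affinity×flux product `σ_j = −(Σ_m μ_m N_mj) · v_j` with
`μ_i = μ⁰_i + ln x_i`; we use the sign convention that makes dissipation
positive for downhill flux. Under detailed-balance rates the two forms are
identical for *any* concentration vector, not only at steady state — the
suite asserts their agreement to 10⁻⁶ relative as a cross-check of the
whole kinetics/energetics pipeline.

## Steady-state integration

Two species are clamped by zeroing their rows of the right-hand side (no
penalty terms); the boundary exchange flux is reported separately as the
net production rate of `b2`, positive when conversion runs `b1 → b2`.
Initial concentrations are `Normal((c1+c2)/2, |c1−c2|)` truncated to
positive by redrawing; with `c1 = c2` every species starts at the common
value.

Integration runs to `t_max = 50000` or until the stationarity residual —
the mean over unclamped species of `(dx_i/dt)²` — drops below `10⁻²⁰`
(detected by a terminal integration event). Non-convergence at `t_max` is
flagged, not raised; the final rates are used as steady-state rates. The
default integrator is BDF with an analytic sparse Jacobian
(`J = N · ∂v/∂x`, assembled per call), chosen because the systems are stiff
at strong drive and an explicit pair needs orders of magnitude more steps;
LSODA and an explicit Dormand–Prince pair are selectable, and the suite
checks that stiff and explicit integrators agree on the steady state.
Default tolerances `rtol = 10⁻⁶`, `atol = 10⁻¹⁰` keep the Eq.-balance
residual `|σ_tot − v ln(c1/c2)|/σ_tot` below ~10⁻⁶ in practice (the
acceptance bound is 10⁻⁴). Rate evaluation clips negative concentrations
to zero; mass action preserves positivity in exact arithmetic and the clip
only damps transient solver undershoot.

Boundary pairs are sampled uniformly per shortest-path distance (up to 50
pairs per occurring distance, fewer when fewer exist) on the largest
connected component of the undirected substrate graph.

## Analysis conventions

* **Mean shortest path** is measured on the *directed* substrate multigraph
  over ordered reachable pairs. The reference ensemble statistics this
  package reproduces are only consistent with the directed measure (ER
  linear ≈ 4.5 ≈ ln N / ln(M/N); the undirected value is ≈ 3.3), so the
  directed convention is the package default.
* **Clustering** is average local clustering on the simple undirected
  projection, nodes of degree < 2 counting 0.
* **Modularity** is Newman modularity of the maximum-modularity cut of the
  walktrap dendrogram (4-step walks) on the simple projection.
* **Cycle census** of a directed multigraph: length 1 = self-loop edge
  instances; length 2 = unordered antiparallel edge-instance pairs between
  distinct nodes; length 4 = simple directed cycles over 4 distinct nodes
  and 4 distinct edge instances, once per rotation class, computed in
  closed form from the multiplicity adjacency matrix
  (`(tr A⁴ − 2Σ_i d_i² + Σ_{ij} (A_{ij}A_{ji})²)/4` with zeroed diagonal,
  `d = diag A²`) and validated against a DFS enumerator. *Cycle excess* is
  the count on the flow-directed graph minus the mean over 10 uniform
  per-reaction redirections of the same network.
* **Dissipation concentration** `f_σ(q)`: the fraction of `Σσ` carried by
  the `⌈qn⌉` most dissipative reactions (default `q = 0.1`).
* **Potential spread**: population standard deviation of `μ` over all
  species divided by `|μ_{b2} − μ_{b1}|`; undefined (signalled) when the
  boundary potentials coincide.
* **Degree–dissipation profile**: per species, the mean σ of the reactions
  containing it; species grouped by substrate-multigraph degree (self-loops
  count twice); per-degree means normalized by the network-wide mean σ.

### Power-law exponent of P(σ)

Per-reaction entropy productions span tens of decades because rate
constants are exponentials of heavy-tailed barriers; the scaling regime
visible in a log-log complementary-cumulative plot is the *upper* part of
the sample. The estimator log-bins the samples between two quantiles and
fits the least-squares slope of log density vs log σ. The default window
covers ccdf values from 0.25 down to 10⁻³ (sample quantiles 0.75–0.999),
i.e. the intermediate region of the cumulative curve; windows reaching into
the low-σ bulk measure a different, flatter regime (slope ≈ −0.9) that is
not a scaling law. The window is a reported field of every fit, never
silent, and a maximum-likelihood estimator (`fit_powerlaw_mle`) is provided
for sensitivity analysis. On pure synthetic power laws the estimator is
window-independent and recovers the exponent to ±0.05 at n = 10⁵.

## Experiment suites and reproducibility

`ExperimentConfig` carries the study conditions; the defaults are the
reference setup (N = 1000; M = 5000 linear or 3000+1000 couplings;
α = 0.1; p = 0.5, h = 8; c1 = 0.1, c2 = 1 or a ladder 0.2–60 at boundary
distance 3; 50 pairs per distance; 10 network samples; t_max = 50000,
residual 10⁻²⁰). Three suites: topology census (ensemble means ± s.d. of
the metrics above), distance scan (mean |flow| vs boundary distance), and
the disequilibrium ladder (flow, f_σ(0.1), σ_μ/Δμ and 2-/4-cycle excess as
c2 rises; one network per model, mirroring the reference usage, though the
config allows more). A master seed spawns per-(model, mode, sample, stage)
child streams via `SeedSequence`, every output row logs the child seeds,
and identical configs give bitwise-identical tables.

The validation suite and the acceptance script run desk-scale reductions:
censuses at the full N = 1000 with 10 samples; dissipation ensembles with 2
networks per model and 10 boundary pairs at distance 4 (~10⁵ pooled σ
values for the linear family); a 4-rung ladder with 5 pairs; a distance
scan with 2 pairs per distance at 8 distances. These sizes were chosen so
the whole suite completes on a single CPU in well under half an hour while
leaving the trend tests clear margins.

## Known limitations

* The nonlinear ensembles' published 2-/4-cycle baselines (and the
  correlated clustering/modularity shifts) are not reproduced: a coupling's
  four substrate edges occupy four distinct node pairs, so within-motif
  antiparallel pairs cannot arise from the documented construction under
  any orientation convention, and the corresponding census cells disagree
  with the reference values by construction, not by sampling error. The
  same counting formulas do reproduce the analytic expectations for
  uniform multigraphs exactly.
* The BA linear clustering coefficient lands near 0.040 (canonical
  preferential attachment gives ≈ 0.035); the reference value 0.0277 is not
  reachable by the standard BA variants tried and the generator is instead
  calibrated on the degree tail and self-loop counts.
* Networks are abstract: no element balance, no temperature dependence, no
  order-3 reactions, no stochastic (Gillespie) dynamics, at most two
  clamped species.
* Frozen reactions (underflowed rate constants) are treated as
  zero-dissipation; their number is ~1 per 5000 reactions.
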