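# rxnflow

Random chemical reaction networks under thermodynamic boundary conditions:
generate them, drive them to a non-equilibrium steady state, and measure
where the dissipation goes.

Real reaction systems — atmospheric photochemistry, combustion, metabolism —
operate far from equilibrium, but thermodynamic data for whole networks is
scarce. `rxnflow` takes the complementary route: it builds *artificial*
reaction networks whose substrate graphs follow four complex-network models
(Erdős–Rényi, Barabási–Albert, Watts–Strogatz, Pan–Sinha), assigns them
thermodynamically consistent mass-action kinetics, and clamps two "boundary"
species at fixed concentrations `c1`, `c2` so a steady conversion flow runs
through the network. That makes the relation between network topology,
flow, entropy production and cycle formation systematically explorable.

## Model in brief

A network of `N` species and `M` reversible reactions (1↔1 `X ⇌ Y` or,
after coupling pairs of linear reactions, 2↔2 `X + Z ⇌ Y + W`) evolves by
mass action,

    dx/dt = N v(x),   v_j = k_j^f Π x_i^{L_ij} − k_j^b Π x_i^{R_ij},

with stoichiometric matrices `N = R − L`. Species carry Gibbs formation
energies `μ⁰ ~ N(0,1)` (units `k_B T = 1`); each reaction draws one
activation energy from the Planck-like law `P(x) ∝ 1/(x³(e^{1/x} − 1))`,
assigned to its exergonic direction with the reverse barrier raised by
`|Δμ⁰|`, so Arrhenius constants `k = e^{−E_a}` obey detailed balance.
Clamping `b1, b2` (with their `μ⁰` set to zero) yields a steady state with
per-reaction entropy production

    σ_j = (v_j⁺ − v_j⁻) ln(v_j⁺ / v_j⁻) ≥ 0,   σ_tot = v ln(c1/c2),

where `v` is the boundary conversion flow. The analysis layer provides the
substrate-graph topology census (path length, clustering, walktrap
modularity, directed 1-/2-/4-cycle counts), the distribution of σ and its
power-law exponent, the dissipation concentration `f_σ(0.1)`, the
chemical-potential spread `σ_μ/Δμ`, and flow-directed cycle excess over
random-direction baselines. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from rxnflow import (
    generate_er, linear_network_from_graph, sample_formation_energies,
    sample_activation_energy, assign_reaction_energetics, rezero_boundary,
    BoundaryCondition, integrate_to_steady_state, substrate_graph,
    sample_boundary_pairs, reaction_entropy_production, dissipation_fraction,
)

rng = np.random.default_rng(0)
g = generate_er(1000, 5000, rng)                       # ER multigraph
net = linear_network_from_graph(g)                     # 5000 reactions X <=> Y
mu0 = sample_formation_energies(net.n_species, rng)
ea = sample_activation_energy(rng, size=net.n_reactions)
thermo = assign_reaction_energetics(net, mu0, ea)

b1, b2, d = sample_boundary_pairs(substrate_graph(net), 1, rng, distances=[4])[0]
thermo = rezero_boundary(thermo, net, b1, b2)
bc = BoundaryCondition(b1, b2, c1=0.1, c2=1.0)
state = integrate_to_steady_state(net, thermo, bc, rng=rng)

sigma = reaction_entropy_production(
    np.maximum(state.v_plus, 1e-300), np.maximum(state.v_minus, 1e-300))
print(f"converged={state.converged}  flow={state.boundary_flow:+.4f}")
print(f"sigma_tot={sigma.sum():.4f}  vs  v*ln(c1/c2)={state.boundary_flow*np.log(0.1):.4f}")
print(f"f_sigma(0.1)={dissipation_fraction(sigma, 0.1):.3f}")
```

prints

```
converged=True  flow=-0.9604
sigma_tot=2.2114  vs  v*ln(c1/c2)=2.2114
f_sigma(0.1)=0.997
```

The flow is negative because the conversion runs from the high-potential
boundary species (`c2 = 1`) to the low one (`c1 = 0.1`); the total entropy
production matches the single-effective-reaction balance `v ln(c1/c2)` to
four digits, and the top 10% of reactions carry essentially all of the
dissipation at this moderate drive.

The same pipeline is scriptable from the shell:

```
rxnflow generate --model WS --mode nonlinear --n 1000 --m 3000 \
        --couplings 1000 --seed 1 --out ws.json
rxnflow simulate --network ws.json --b1 3 --b2 810 --c1 0.1 --c2 1.0 \
        --seed 2 --out run.json
rxnflow analyze --run run.json --network ws.json --out analysis.csv
rxnflow census --seed 5 --out census.csv
```

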