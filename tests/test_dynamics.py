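"""Mass-action dynamics: rates, clamped integration, boundary sampling."""

import numpy as np
import pytest
from scipy import stats

from rxnflow.graphs import generate_er
from rxnflow.reactions import Reaction, ReactionNetwork, linear_network_from_graph, substrate_graph
from rxnflow.thermo import (
    assign_reaction_energetics,
    sample_activation_energy,
    sample_formation_energies,
    rezero_boundary,
)
from rxnflow.dynamics import (
    BoundaryCondition,
    boundary_flow,
    initialize_concentrations,
    integrate_to_steady_state,
    ode_rhs,
    one_way_rates,
    sample_boundary_pairs,
)


def _unit_thermo(net):
    return assign_reaction_energetics(
        net, np.zeros(net.n_species), np.zeros(net.n_reactions)
    )


def test_one_way_rates_examples():
    net = ReactionNetwork(4, [Reaction((0, 2), (1, 3))])
    vp, vm = one_way_rates(net, _unit_thermo(net), np.ones(4))
    assert vp[0] == vm[0] == 1.0
    net2 = ReactionNetwork(3, [Reaction((0, 0), (1, 2))])
    vp, _ = one_way_rates(net2, _unit_thermo(net2), np.array([2.0, 1.0, 1.0]))
    assert vp[0] == 4.0  # x_a^2
    with pytest.raises(ValueError):
        one_way_rates(net, _unit_thermo(net), np.array([-1.0, 1, 1, 1]))


def test_rates_balance_at_boltzmann_concentrations():
    rng = np.random.default_rng(1)
    net = linear_network_from_graph(generate_er(15, 40, rng))
    mu0 = sample_formation_energies(15, rng)
    ea = sample_activation_energy(rng, size=40)
    th = assign_reaction_energetics(net, mu0, ea)
    vp, vm = one_way_rates(net, th, np.exp(-mu0))
    ok = vp > 0
    assert np.allclose(vp[ok], vm[ok], rtol=1e-12)


def test_ode_rhs_conservation_and_chain_formula():
    rng = np.random.default_rng(2)
    net = linear_network_from_graph(generate_er(10, 30, rng))
    th = _unit_thermo(net)
    x = rng.uniform(0.5, 2, 10)
    assert ode_rhs(net, th, x).sum() == pytest.approx(0.0, abs=1e-12)
    # chain a<=>b<=>c clamped at a, c: db/dt = c1 + c2 - 2 x_b
    chain = ReactionNetwork(3, [Reaction((0,), (1,)), Reaction((1,), (2,))])
    bc = BoundaryCondition(0, 2, 0.1, 1.0)
    x = np.array([0.1, 0.3, 1.0])
    dx = ode_rhs(chain, _unit_thermo(chain), x, bc)
    assert dx[0] == dx[2] == 0.0
    assert dx[1] == pytest.approx(0.1 + 1.0 - 2 * 0.3)


def test_initialize_concentrations_contract():
    rng = np.random.default_rng(3)
    bc_eq = BoundaryCondition(0, 1, 0.5, 0.5)
    x = initialize_concentrations(100, bc_eq, rng)
    assert np.all(x == 0.5)
    bc = BoundaryCondition(0, 1, 0.1, 1.0)
    x = initialize_concentrations(10_000, bc, rng)
    assert np.all(x > 0)
    assert x[0] == 0.1 and x[1] == 1.0
    # truncated-normal mean: Normal(0.55, 0.9) conditioned on > 0
    a = (0 - 0.55) / 0.9
    expect = stats.truncnorm.mean(a, np.inf, loc=0.55, scale=0.9)
    assert x[2:].mean() == pytest.approx(expect, rel=0.02)


def test_two_species_closed_form():
    """a<=>b both clamped, unit constants: v = c1 - c2 = -0.9."""
    net = ReactionNetwork(2, [Reaction((0,), (1,))])
    bc = BoundaryCondition(0, 1, 0.1, 1.0)
    st = integrate_to_steady_state(
        net, _unit_thermo(net), bc, rng=np.random.default_rng(0)
    )
    assert st.converged
    assert st.boundary_flow == pytest.approx(-0.9, abs=1e-9)
    sigma_tot = (st.v_plus - st.v_minus) @ np.log(st.v_plus / st.v_minus)
    assert sigma_tot == pytest.approx(0.9 * np.log(10), rel=1e-9)


def test_chain_steady_state_linear_algebra():
    chain = ReactionNetwork(3, [Reaction((0,), (1,)), Reaction((1,), (2,))])
    bc = BoundaryCondition(0, 2, 0.1, 1.0)
    st = integrate_to_steady_state(
        chain, _unit_thermo(chain), bc, rng=np.random.default_rng(1)
    )
    assert st.converged
    assert st.x[1] == pytest.approx(0.55, abs=1e-6)
    assert abs(st.boundary_flow) == pytest.approx(0.45, abs=1e-6)


def test_closed_network_conserves_mass_and_reaches_boltzmann():
    rng = np.random.default_rng(5)
    net = linear_network_from_graph(generate_er(20, 50, rng))
    mu0 = sample_formation_energies(20, rng)
    ea = np.minimum(sample_activation_energy(rng, size=50), 20.0)
    th = assign_reaction_energetics(net, mu0, ea)
    x0 = rng.uniform(0.5, 2.0, 20)
    st = integrate_to_steady_state(net, th, boundary=None, x0=x0, rng=rng, t_max=1e7)
    assert st.converged
    assert st.x.sum() == pytest.approx(x0.sum(), rel=1e-9)
    ok = st.v_plus > 0
    assert np.allclose(st.v_plus[ok], st.v_minus[ok], rtol=1e-6)
    # stationary concentrations are Boltzmann up to one constant per component
    import igraph as ig

    g = substrate_graph(net).to_igraph(directed=False)
    for comp in g.connected_components():
        if len(comp) < 2:
            continue
        ratio = st.x[comp] / np.exp(-mu0[comp])
        assert ratio.max() / ratio.min() == pytest.approx(1.0, rel=1e-6)


def test_boltzmann_start_converges_immediately():
    rng = np.random.default_rng(6)
    net = linear_network_from_graph(generate_er(15, 40, rng))
    mu0 = sample_formation_energies(15, rng)
    th = assign_reaction_energetics(net, mu0, np.ones(40))
    st = integrate_to_steady_state(
        net, th, boundary=None, x0=np.exp(-mu0), rng=rng
    )
    assert st.converged and st.t_final == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_integrator_independence(seed):
    """Stiff and explicit integrators agree on the steady state."""
    rng = np.random.default_rng(100 + seed)
    net = linear_network_from_graph(generate_er(25, 70, rng))
    mu0 = sample_formation_energies(25, rng)
    ea = np.minimum(sample_activation_energy(rng, size=70), 15.0)
    th = assign_reaction_energetics(net, mu0, ea)
    th = rezero_boundary(th, net, 0, 1)
    bc = BoundaryCondition(0, 1, 0.1, 1.0)
    x0 = initialize_concentrations(25, bc, np.random.default_rng(seed))
    res = {}
    for method in ("auto", "rk45"):
        st = integrate_to_steady_state(
            net, th, bc, x0=x0.copy(), method=method, t_max=5000.0
        )
        res[method] = st
    assert res["auto"].boundary_flow == pytest.approx(
        res["rk45"].boundary_flow, rel=1e-3, abs=1e-7
    )


@pytest.mark.parametrize("seed", range(5))
def test_flow_antisymmetry_linear(seed):
    """Swapping the boundary roles negates the flow in linear networks."""
    rng = np.random.default_rng(200 + seed)
    net = linear_network_from_graph(generate_er(20, 60, rng))
    mu0 = sample_formation_energies(20, rng)
    ea = np.minimum(sample_activation_energy(rng, size=60), 15.0)
    th = rezero_boundary(assign_reaction_energetics(net, mu0, ea), net, 0, 1)
    f = {}
    for tag, (b1, b2, c1, c2) in {
        "fwd": (0, 1, 0.1, 1.0),
        "rev": (1, 0, 1.0, 0.1),
    }.items():
        bc = BoundaryCondition(b1, b2, c1, c2)
        st = integrate_to_steady_state(net, th, bc, rng=np.random.default_rng(seed))
        f[tag] = st.boundary_flow
    assert f["fwd"] == pytest.approx(-f["rev"], rel=1e-5, abs=1e-12)


def test_boundary_flow_conservation():
    """Steady production at b2 equals consumption at b1."""
    rng = np.random.default_rng(8)
    net = linear_network_from_graph(generate_er(30, 90, rng))
    mu0 = sample_formation_energies(30, rng)
    ea = np.minimum(sample_activation_energy(rng, size=90), 15.0)
    th = rezero_boundary(assign_reaction_energetics(net, mu0, ea), net, 3, 9)
    bc = BoundaryCondition(3, 9, 0.1, 1.0)
    st = integrate_to_steady_state(net, th, bc, rng=rng)
    from rxnflow.reactions import stoichiometric_matrices

    _, _, N = stoichiometric_matrices(net)
    prod = np.asarray(N @ st.v_net).ravel()
    assert prod[9] == pytest.approx(-prod[3], rel=1e-6, abs=1e-12)
    assert boundary_flow(st, net, bc) == pytest.approx(st.boundary_flow)


def _bfs_distance(edges, n, src):
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    dist = [-1] * n
    dist[src] = 0
    queue = [src]
    while queue:
        nxt = []
        for u in queue:
            for w in adj[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        queue = nxt
    return dist


def test_sample_boundary_pairs_against_bfs_oracle():
    rng = np.random.default_rng(9)
    g = generate_er(60, 150, rng)
    pairs = sample_boundary_pairs(g, pairs_per_distance=10, rng=rng)
    assert pairs
    for b1, b2, d in pairs:
        assert _bfs_distance(g.edges.tolist(), 60, b1)[b2] == d


def test_sample_boundary_pairs_path_graph():
    from rxnflow.graphs import DirectedMultigraph

    g = DirectedMultigraph(3, np.array([[0, 1], [1, 2]]))
    pairs = sample_boundary_pairs(g, pairs_per_distance=50, rng=np.random.default_rng(0))
    by_d = {}
    for b1, b2, d in pairs:
        by_d.setdefault(d, []).append((b1, b2))
    assert set(by_d) == {1, 2}
    assert len(by_d[1]) == 2 and len(by_d[2]) == 1  # fewer pairs than requested
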