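"""Entropy production, power-law fitting, cycle censuses, topology metrics."""

import numpy as np
import pytest

from rxnflow.graphs import DirectedMultigraph, generate_er
from rxnflow.reactions import (
    Reaction,
    ReactionNetwork,
    linear_network_from_graph,
    stoichiometric_matrices,
)
from rxnflow.thermo import (
    assign_reaction_energetics,
    rezero_boundary,
    sample_activation_energy,
    sample_formation_energies,
)
from rxnflow.dynamics import BoundaryCondition, integrate_to_steady_state
from rxnflow.analysis import (
    chemical_potentials,
    count_directed_cycles,
    cycle_excess,
    degree_dissipation_profile,
    dissipation_fraction,
    entropy_production_from_potentials,
    fit_powerlaw_exponent,
    fit_powerlaw_mle,
    potential_spread,
    reaction_entropy_production,
    topology_metrics,
    total_entropy_check,
)


def test_entropy_production_examples():
    assert reaction_entropy_production([3.0], [3.0])[0] == 0.0
    assert reaction_entropy_production([np.e], [1.0])[0] == pytest.approx(np.e - 1)
    assert np.all(reaction_entropy_production([0.5, 2.0], [1.5, 0.1]) >= 0)
    with pytest.raises(ValueError):
        reaction_entropy_production([0.0], [1.0])


def test_rate_and_potential_entropy_forms_agree():
    """(v+-v-)ln(v+/v-) equals -(N^T mu) v under detailed-balance rates."""
    rng = np.random.default_rng(4)
    net = linear_network_from_graph(generate_er(20, 60, rng))
    mu0 = sample_formation_energies(20, rng)
    ea = np.minimum(sample_activation_energy(rng, size=60), 15.0)
    th = assign_reaction_energetics(net, mu0, ea)
    x = rng.uniform(0.2, 2.0, 20)  # any state, not only steady
    from rxnflow.dynamics import one_way_rates

    vp, vm = one_way_rates(net, th, x)
    s1 = reaction_entropy_production(vp, vm)
    _, _, N = stoichiometric_matrices(net)
    s2 = entropy_production_from_potentials(chemical_potentials(mu0, x), N, vp - vm)
    assert np.allclose(s1, s2, rtol=1e-10, atol=1e-12)


def test_total_entropy_check_direct_reaction():
    net = ReactionNetwork(2, [Reaction((0,), (1,))])
    th = assign_reaction_energetics(net, np.zeros(2), np.zeros(1))
    bc = BoundaryCondition(0, 1, 0.1, 1.0)
    st = integrate_to_steady_state(net, th, bc, rng=np.random.default_rng(0))
    sigma_tot, res = total_entropy_check(st, bc)
    assert sigma_tot == pytest.approx(0.9 * np.log(10), rel=1e-9)
    assert res < 1e-8


def test_total_entropy_check_equilibrium_zero():
    net = ReactionNetwork(2, [Reaction((0,), (1,))])
    th = assign_reaction_energetics(net, np.zeros(2), np.zeros(1))
    bc = BoundaryCondition(0, 1, 1.0, 1.0)
    st = integrate_to_steady_state(net, th, bc, rng=np.random.default_rng(0))
    sigma_tot, res = total_entropy_check(st, bc)
    assert sigma_tot == pytest.approx(0.0, abs=1e-15)
    assert res == 0.0


def test_chemical_potentials_examples():
    assert chemical_potentials(np.zeros(2), np.ones(2)).tolist() == [0.0, 0.0]
    mu = chemical_potentials(np.zeros(3), np.array([0.1, 1.0, 2.0]))
    assert mu[0] == pytest.approx(np.log(0.1))
    with pytest.raises(ValueError):
        chemical_potentials(np.zeros(1), np.zeros(1))
    # Boltzmann closed state: all potentials equal
    mu0 = np.array([0.3, -1.2, 0.7])
    mu = chemical_potentials(mu0, 2.0 * np.exp(-mu0))
    assert np.allclose(mu, mu[0])


def test_potential_spread():
    bc = BoundaryCondition(0, 1, 0.1, 1.0)
    mu = np.full(100, 2.5)
    mu[1] = 3.5
    assert potential_spread(mu, bc) > 0
    # uniform distribution between the boundary potentials -> ~ 1/sqrt(12)
    rng = np.random.default_rng(0)
    mu = rng.uniform(0.0, 1.0, 1_000_000)
    mu[0], mu[1] = 0.0, 1.0
    assert potential_spread(mu, bc) == pytest.approx(1 / np.sqrt(12), rel=5e-3)
    with pytest.raises(ValueError):
        potential_spread(np.zeros(5), bc)


def test_dissipation_fraction():
    assert dissipation_fraction(np.ones(10), 0.1) == pytest.approx(0.1)
    sigma = np.zeros(10)
    sigma[3] = 5.0
    assert dissipation_fraction(sigma, 0.1) == pytest.approx(1.0)
    assert dissipation_fraction(np.arange(1, 11), 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        dissipation_fraction(np.zeros(4), 0.1)
    with pytest.raises(ValueError):
        dissipation_fraction(np.ones(4), 0.0)


def test_powerlaw_recovery_pareto():
    """Density exponent -1.5 of a Pareto sample recovered within 0.05."""
    rng = np.random.default_rng(7)
    u = rng.random(100_000)
    x = (1 - u) ** (-1 / 0.5)  # density 0.5 x^-1.5 on [1, inf)
    fit = fit_powerlaw_exponent(x)
    assert fit.exponent == pytest.approx(-1.5, abs=0.05)
    assert fit.r_squared > 0.99
    assert fit_powerlaw_mle(x, xmin=1.0) == pytest.approx(-1.5, abs=0.02)


def test_powerlaw_flags_non_powerlaw_control():
    """An exponential sample yields a visibly poor straight-line fit."""
    rng = np.random.default_rng(8)
    x = rng.exponential(1.0, 100_000)
    window = (0.10, 0.999)  # wide window exposes the log-log curvature
    fit = fit_powerlaw_exponent(x, window=window)
    assert fit.r_squared < 0.95
    u = rng.random(100_000)
    pareto = (1 - u) ** (-1 / 0.5)
    assert fit_powerlaw_exponent(pareto, window=window).r_squared > fit.r_squared
    with pytest.raises(ValueError):
        fit_powerlaw_exponent(np.ones(10))  # too few samples


# ---------------------------------------------------------------------------
# cycles


from .oracles import brute_force_cycles as _brute_force_cycles


def test_cycle_counter_trivial_cases():
    g = DirectedMultigraph(2, np.array([[0, 1], [1, 0]]))
    assert count_directed_cycles(g, 2) == 1
    square = DirectedMultigraph(4, np.array([[0, 1], [1, 2], [2, 3], [3, 0]]))
    assert count_directed_cycles(square, 4) == 1
    assert count_directed_cycles(square, 2) == 0
    loops = DirectedMultigraph(2, np.array([[0, 0], [0, 0], [1, 1]]))
    assert count_directed_cycles(loops, 1) == 3
    with pytest.raises(ValueError):
        count_directed_cycles(square, 3)


@pytest.mark.parametrize("length", [1, 2, 4])
def test_cycle_counter_matches_brute_force(length):
    """Closed-form multigraph counter equals DFS enumeration on 100 graphs."""
    rng = np.random.default_rng(31)
    for _ in range(100):
        n = int(rng.integers(4, 31))
        m = int(rng.integers(n, 4 * n))
        g = generate_er(n, m, rng)
        assert count_directed_cycles(g, length) == _brute_force_cycles(g, length)


def test_cycle_excess_self_consistency():
    """Random-direction 'observed' graphs show excess ~ 0 within baseline sd."""
    rng = np.random.default_rng(33)
    net = linear_network_from_graph(generate_er(100, 400, rng))
    rates = rng.choice([-1.0, 1.0], size=400)
    exc = cycle_excess(net, rates, reps=20, rng=rng)
    for l in (2, 4):
        sd = max(exc[l]["baseline_sd"], 1.0)
        assert abs(exc[l]["excess"]) < 4 * sd


def test_topology_metrics_closed_forms():
    # bidirectional 4-cycle: directed distances match the undirected ring
    ring = DirectedMultigraph(
        4, np.array([[0, 1], [1, 2], [2, 3], [3, 0], [1, 0], [2, 1], [3, 2], [0, 3]])
    )
    met = topology_metrics(ring)
    assert met["mean_shortest_path"] == pytest.approx(4 / 3)
    assert met["clustering"] == 0.0
    # complete graph K4
    k4 = DirectedMultigraph(
        4, np.array([[u, v] for u in range(4) for v in range(u + 1, 4)])
    )
    assert topology_metrics(k4)["clustering"] == pytest.approx(1.0)


def test_walktrap_modularity_two_cliques():
    """Two K5 joined by one edge: Q of the 2-community split is 0.4524."""
    edges = []
    for base in (0, 5):
        edges += [[base + u, base + v] for u in range(5) for v in range(u + 1, 5)]
    edges.append([0, 5])
    g = DirectedMultigraph(10, np.array(edges))
    q_expected = 2 * (10 / 21 - (21 / 42) ** 2)
    assert topology_metrics(g)["modularity"] == pytest.approx(q_expected, abs=1e-6)


def test_degree_dissipation_profile_uniform_and_single():
    rng = np.random.default_rng(35)
    net = linear_network_from_graph(generate_er(30, 90, rng))
    prof = degree_dissipation_profile(net, np.ones(90))
    assert all(v == pytest.approx(1.0) for v in prof.values())
    single = ReactionNetwork(2, [Reaction((0,), (1,))])
    prof = degree_dissipation_profile(single, np.array([2.0]))
    assert prof == {1: pytest.approx(1.0)}
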