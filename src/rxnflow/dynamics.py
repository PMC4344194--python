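"""Mass-action dynamics with two clamped boundary species.

The ODE is ``dx/dt = N (v_+ - v_-)`` with one-way rates
``v_+ = k_fwd prod_i x_i^L_ij`` and ``v_- = k_bwd prod_i x_i^R_ij``; the two
boundary species are clamped by zeroing their rows of the right-hand side.
Integration runs until the mean square concentration change per species and
unit time drops below a residual tolerance, or until ``t_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .reactions import ReactionNetwork, stoichiometric_matrices, substrate_edges
from .thermo import ThermoAssignment

__all__ = [
    "BoundaryCondition",
    "SteadyState",
    "MassActionKinetics",
    "one_way_rates",
    "ode_rhs",
    "initialize_concentrations",
    "integrate_to_steady_state",
    "boundary_flow",
    "sample_boundary_pairs",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoundaryCondition:
    """Two clamped species with fixed positive concentrations."""

    b1: int
    b2: int
    c1: float
    c2: float

    def __post_init__(self):
        if self.b1 == self.b2:
            raise ValueError("boundary species must differ")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("boundary concentrations must be positive")


@dataclass
class SteadyState:
    """Outcome of a clamped steady-state integration."""

    x: np.ndarray
    v_plus: np.ndarray
    v_minus: np.ndarray
    boundary_flow: float
    converged: bool
    t_final: float
    residual: float

    @property
    def v_net(self) -> np.ndarray:
        return self.v_plus - self.v_minus


class MassActionKinetics:
    """Vectorized rate/rhs/Jacobian evaluation for order-<=2 networks.

    Reactant and product species are stored as index arrays (with a padding
    slot holding concentration 1 for first-order sides), so one-way rates are
    two gathers and a product.
    """

    def __init__(self, net: ReactionNetwork, thermo: ThermoAssignment):
        n, m = net.n_species, net.n_reactions
        self.n_species, self.n_reactions = n, m
        idx_l = np.full((m, 2), n, dtype=np.int64)
        idx_r = np.full((m, 2), n, dtype=np.int64)
        for j, rx in enumerate(net.reactions):
            idx_l[j, : rx.order] = rx.reactants
            idx_r[j, : rx.order] = rx.products
        self.idx_l, self.idx_r = idx_l, idx_r
        self.k_fwd = thermo.k_fwd
        self.k_bwd = thermo.k_bwd
        _, _, N = stoichiometric_matrices(net)
        self.N = N

    def _pad(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([np.maximum(x, 0.0), [1.0]])

    def rates(self, x: np.ndarray):
        xp = self._pad(x)
        v_plus = self.k_fwd * xp[self.idx_l[:, 0]] * xp[self.idx_l[:, 1]]
        v_minus = self.k_bwd * xp[self.idx_r[:, 0]] * xp[self.idx_r[:, 1]]
        return v_plus, v_minus

    def rhs(self, x: np.ndarray) -> np.ndarray:
        v_plus, v_minus = self.rates(x)
        return self.N @ (v_plus - v_minus)

    def jacobian(self, x: np.ndarray) -> sp.csr_matrix:
        """Analytic ``d(N v)/dx`` as a sparse matrix."""
        n, m = self.n_species, self.n_reactions
        xp = self._pad(x)
        rows, cols, vals = [], [], []
        for sign, idx, k in (
            (1.0, self.idx_l, self.k_fwd),
            (-1.0, self.idx_r, self.k_bwd),
        ):
            a, b = idx[:, 0], idx[:, 1]
            for this, other in ((a, b), (b, a)):
                mask = this < n
                rows.append(np.arange(m)[mask])
                cols.append(this[mask])
                vals.append((sign * k * xp[other])[mask])
        D = sp.coo_matrix(
            (
                np.concatenate(vals),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(m, n),
        ).tocsr()
        return (self.N @ D).tocsr()


def one_way_rates(net: ReactionNetwork, thermo: ThermoAssignment, x: np.ndarray):
    """Per-reaction one-way mass-action rates ``(v_plus, v_minus)``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be nonnegative")
    return MassActionKinetics(net, thermo).rates(x)


def ode_rhs(
    net: ReactionNetwork,
    thermo: ThermoAssignment,
    x: np.ndarray,
    boundary: Optional[BoundaryCondition] = None,
) -> np.ndarray:
    """``dx/dt = N (v_+ - v_-)`` with clamped rows zeroed (if a boundary is given)."""
    dx = MassActionKinetics(net, thermo).rhs(np.asarray(x, dtype=float))
    if boundary is not None:
        dx[[boundary.b1, boundary.b2]] = 0.0
    return dx


def initialize_concentrations(
    n_species: int, boundary: BoundaryCondition, rng: np.random.Generator
) -> np.ndarray:
    """Strictly positive normal draws, boundary entries clamped.

    Concentrations are drawn from Normal((c1+c2)/2, |c1-c2|), redrawing any
    non-positive values; with c1 == c2 every species starts at that value.
    """
    mean = 0.5 * (boundary.c1 + boundary.c2)
    sd = abs(boundary.c1 - boundary.c2)
    if sd == 0:
        x = np.full(n_species, mean)
    else:
        x = rng.normal(mean, sd, size=n_species)
        bad = x <= 0
        while np.any(bad):
            x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = x <= 0
    x[boundary.b1] = boundary.c1
    x[boundary.b2] = boundary.c2
    return x


def integrate_to_steady_state(
    net: ReactionNetwork,
    thermo: ThermoAssignment,
    boundary: Optional[BoundaryCondition] = None,
    t_max: float = 50000.0,
    residual_tol: float = 1e-20,
    rng: Optional[np.random.Generator] = None,
    x0: Optional[np.ndarray] = None,
    method: str = "auto",
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> SteadyState:
    """Integrate the clamped ODE until stationarity or ``t_max``.

    The stationarity residual is the mean over unclamped species of
    ``(dx_i/dt)^2``; integration stops once it falls below ``residual_tol``.
    ``method`` is ``"auto"`` (stiff-capable BDF with the analytic sparse
    Jacobian), ``"lsoda"`` or ``"rk45"`` (explicit Dormand–Prince pair).
    Non-convergence at ``t_max`` is reported, not raised.
    """
    if rng is None:
        rng = np.random.default_rng()
    kin = MassActionKinetics(net, thermo)
    if boundary is not None:
        mask = np.ones(net.n_species, dtype=bool)
        mask[[boundary.b1, boundary.b2]] = False
    else:
        mask = np.ones(net.n_species, dtype=bool)
    if x0 is None:
        if boundary is None:
            raise ValueError("x0 is required for unclamped integration")
        x0 = initialize_concentrations(net.n_species, boundary, rng)
    x0 = np.asarray(x0, dtype=float).copy()
    if boundary is not None:
        x0[boundary.b1] = boundary.c1
        x0[boundary.b2] = boundary.c2

    def fun(t, x):
        dx = kin.rhs(x)
        if boundary is not None:
            dx[[boundary.b1, boundary.b2]] = 0.0
        return dx

    def residual_of(x):
        dx = fun(0.0, x)
        return float(np.mean(dx[mask] ** 2)) if mask.any() else 0.0

    if residual_of(x0) < residual_tol:
        v_plus, v_minus = kin.rates(x0)
        return SteadyState(
            x=x0,
            v_plus=v_plus,
            v_minus=v_minus,
            boundary_flow=_flow(kin, v_plus - v_minus, boundary),
            converged=True,
            t_final=0.0,
            residual=residual_of(x0),
        )

    def event(t, x):
        return np.log10(residual_of(x) + 1e-300) - np.log10(residual_tol)

    event.terminal = True
    event.direction = -1

    kwargs: dict = {}
    if method == "auto":
        ivp_method = "BDF"

        def jac(t, x):
            J = kin.jacobian(x).tolil()
            if boundary is not None:
                J[boundary.b1, :] = 0.0
                J[boundary.b2, :] = 0.0
            return J.tocsc()

        kwargs["jac"] = jac
    elif method == "lsoda":
        ivp_method = "LSODA"
    elif method == "rk45":
        ivp_method = "RK45"
    else:
        raise ValueError(f"unknown method {method!r}")

    sol = solve_ivp(
        fun,
        (0.0, t_max),
        x0,
        method=ivp_method,
        events=event,
        rtol=rtol,
        atol=atol,
        **kwargs,
    )
    if not sol.success and sol.status != 1:
        raise IntegrationError(f"integration failed: {sol.message}")
    x = sol.y[:, -1]
    if not np.all(np.isfinite(x)):
        raise IntegrationError(
            f"non-finite state at t={sol.t[-1]:.3g}; min={np.nanmin(x):.3g}"
        )
    x = np.maximum(x, 0.0)
    if boundary is not None:
        x[boundary.b1] = boundary.c1
        x[boundary.b2] = boundary.c2
    res = residual_of(x)
    hit_event = bool(sol.t_events and len(sol.t_events[0]) > 0)
    v_plus, v_minus = kin.rates(x)
    return SteadyState(
        x=x,
        v_plus=v_plus,
        v_minus=v_minus,
        boundary_flow=_flow(kin, v_plus - v_minus, boundary),
        converged=hit_event or bool(res < residual_tol),
        t_final=float(sol.t[-1]),
        residual=res,
    )


def _flow(kin: MassActionKinetics, v_net: np.ndarray, boundary) -> float:
    if boundary is None:
        return 0.0
    return float((kin.N @ v_net)[boundary.b2])


def boundary_flow(
    state: SteadyState, net: ReactionNetwork, boundary: BoundaryCondition
) -> float:
    """Net production rate of ``b2`` (positive when conversion runs b1 -> b2)."""
    _, _, N = stoichiometric_matrices(net)
    return float((N @ state.v_net)[boundary.b2])


def sample_boundary_pairs(
    graph,
    pairs_per_distance: int = 50,
    rng: Optional[np.random.Generator] = None,
    distances: Optional[list] = None,
):
    """Uniform node pairs at each shortest-path distance of the substrate graph.

    ``graph`` is a :class:`~rxnflow.graphs.DirectedMultigraph` (treated as
    undirected) or a ReactionNetwork.  Only the largest connected component
    is used.  Returns a list of ``(b1, b2, d)`` with at most
    ``pairs_per_distance`` pairs per occurring distance ``d >= 1``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(graph, ReactionNetwork):
        edges = substrate_edges(graph)
        n = graph.n_species
    else:
        edges = graph.edges
        n = graph.n_nodes
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    comp = g.connected_components()
    giant = max(comp, key=len)
    sub = g.induced_subgraph(giant)
    dmat = np.array(sub.distances(), dtype=float)
    giant = np.asarray(giant)
    out = []
    dvals = np.unique(dmat[np.isfinite(dmat) & (dmat >= 1)]).astype(int)
    if distances is not None:
        dvals = [d for d in dvals if d in set(distances)]
    for d in dvals:
        ii, jj = np.nonzero(np.triu(dmat == d, k=1))
        if ii.size == 0:
            continue
        take = min(pairs_per_distance, ii.size)
        sel = rng.choice(ii.size, size=take, replace=False)
        for s in sel:
            out.append((int(giant[ii[s]]), int(giant[jj[s]]), int(d)))
    return out
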