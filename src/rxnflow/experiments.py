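"""End-to-end experiment suites.

Three orchestrated studies, all driven by one :class:`ExperimentConfig` and
a single master seed:

* topology census — ensembles of networks per model/mode with topology
  metrics and cycle counts (mean ± s.d.);
* distance scan — steady-state boundary flow versus the shortest-path
  distance between the boundary species;
* disequilibrium ladder — nonlinear networks driven harder and harder by
  raising one boundary concentration, tracking flow, dissipation
  concentration, chemical-potential spread and cycle excess.

Every emitted row carries the seeds needed to regenerate that run alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._seeding import child_rng, child_seed
from .analysis import (
    chemical_potentials,
    count_directed_cycles,
    cycle_excess,
    dissipation_fraction,
    potential_spread,
    topology_metrics,
    total_entropy_check,
)
from .dynamics import (
    BoundaryCondition,
    integrate_to_steady_state,
    sample_boundary_pairs,
)
from .graphs import generate_ba, generate_er, generate_ps, generate_ws
from .reactions import (
    ReactionNetwork,
    couple_reactions,
    linear_network_from_graph,
    linear_network_from_substrate,
    substrate_graph,
)
from .thermo import (
    assign_reaction_energetics,
    rezero_boundary,
    sample_activation_energy,
    sample_formation_energies,
)

__all__ = [
    "ExperimentConfig",
    "build_graph",
    "build_network",
    "attach_thermodynamics",
    "simulate_pair",
    "run_topology_census",
    "run_dissipation_ensemble",
    "run_distance_scan",
    "run_disequilibrium_ladder",
]

MODELS = ("ER", "BA", "WS", "PS")
_MODEL_INDEX = {m: i for i, m in enumerate(MODELS)}
_MODE_INDEX = {"linear": 0, "nonlinear": 1, "linear_from_nonlinear_substrate": 2}


@dataclass
class ExperimentConfig:
    """Study conditions; defaults reproduce the reference setup."""

    models: tuple = MODELS
    mode: str = "linear"
    n_species: int = 1000
    m_linear: int = 5000          # reactions in a linear network
    m_pre_coupling: int = 3000    # linear reactions before coupling
    n_couplings: int = 1000
    alpha: float = 0.1            # WS rewiring fraction
    ps_p: float = 0.5
    ps_h: int = 8
    c1: float = 0.1
    c2: float = 1.0
    ladder_c2: tuple = (0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 60.0)
    ladder_distance: int = 3
    pairs_per_distance: int = 50
    n_network_samples: int = 10
    t_max: float = 50000.0
    residual_tol: float = 1e-20
    baseline_reps: int = 10
    integrator: str = "auto"
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("models", "ladder_c2"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def build_graph(model: str, cfg: ExperimentConfig, rng: np.random.Generator, m: int):
    if model == "ER":
        return generate_er(cfg.n_species, m, rng)
    if model == "BA":
        return generate_ba(cfg.n_species, m, rng)
    if model == "WS":
        return generate_ws(cfg.n_species, m, cfg.alpha, rng)
    if model == "PS":
        return generate_ps(cfg.n_species, m, cfg.ps_p, cfg.ps_h, rng)
    raise ValueError(f"unknown model {model!r}")


def build_network(
    model: str, mode: str, cfg: ExperimentConfig, sample: int
) -> ReactionNetwork:
    """Deterministically build one network sample for a model/mode."""
    mseed = (cfg.master_seed, _MODEL_INDEX[model], _MODE_INDEX[mode], sample)
    if mode == "linear":
        g = build_graph(model, cfg, child_rng(*mseed, 0), cfg.m_linear)
        net = linear_network_from_graph(g)
    else:
        g = build_graph(model, cfg, child_rng(*mseed, 0), cfg.m_pre_coupling)
        net = couple_reactions(
            linear_network_from_graph(g),
            cfg.n_couplings,
            rng=child_rng(*mseed, 1),
        )
        if mode == "linear_from_nonlinear_substrate":
            net = linear_network_from_substrate(net)
    net.meta["network_seed"] = child_seed(*mseed, 0)
    net.meta["model"] = model
    net.meta["mode"] = mode
    net.meta["sample"] = sample
    return net


def attach_thermodynamics(net: ReactionNetwork, cfg: ExperimentConfig, sample: int):
    """Sample formation and activation energies for one network."""
    model = net.meta.get("model", "ER")
    mode = net.meta.get("mode", cfg.mode)
    path = (cfg.master_seed, _MODEL_INDEX[model], _MODE_INDEX[mode], sample)
    rng = child_rng(*path, 2)
    mu0 = sample_formation_energies(net.n_species, rng)
    ea = sample_activation_energy(rng, size=net.n_reactions)
    thermo = assign_reaction_energetics(net, mu0, ea)
    return thermo, child_seed(*path, 2)


def simulate_pair(
    net: ReactionNetwork,
    thermo,
    b1: int,
    b2: int,
    cfg: ExperimentConfig,
    init_rng: np.random.Generator,
    c2: Optional[float] = None,
):
    """Re-zero the boundary, integrate, and return ``(state, thermo_zeroed)``."""
    boundary = BoundaryCondition(b1, b2, cfg.c1, cfg.c2 if c2 is None else c2)
    thermo_z = rezero_boundary(thermo, net, b1, b2)
    state = integrate_to_steady_state(
        net,
        thermo_z,
        boundary,
        t_max=cfg.t_max,
        residual_tol=cfg.residual_tol,
        rng=init_rng,
        method=cfg.integrator,
    )
    return state, thermo_z, boundary


def _safe_sigma(state) -> np.ndarray:
    """Per-reaction entropy production, zero where a one-way rate underflows."""
    vp, vm = state.v_plus, state.v_minus
    sigma = np.zeros_like(vp)
    ok = (vp > 0) & (vm > 0)
    sigma[ok] = (vp[ok] - vm[ok]) * np.log(vp[ok] / vm[ok])
    return sigma


# ---------------------------------------------------------------------------
# suites


def run_topology_census(
    cfg: ExperimentConfig, modes: Iterable[str] = ("linear", "nonlinear")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Topology metrics and cycle counts, mean ± s.d. over the ensemble.

    Returns ``(summary, samples)`` data frames; cycle counts are taken on
    the directed substrate graph with the as-generated reaction directions.
    """
    rows = []
    for model in cfg.models:
        for mode in modes:
            for sample in range(cfg.n_network_samples):
                net = build_network(model, mode, cfg, sample)
                sub = substrate_graph(net)
                met = topology_metrics(sub)
                rows.append(
                    {
                        "model": model,
                        "mode": mode,
                        "sample": sample,
                        "network_seed": net.meta["network_seed"],
                        "n_species": net.n_species,
                        "n_edges": sub.n_edges,
                        **met,
                        "cycles_1": count_directed_cycles(sub, 1),
                        "cycles_2": count_directed_cycles(sub, 2),
                        "cycles_4": count_directed_cycles(sub, 4),
                    }
                )
    samples = pd.DataFrame(rows)
    metrics = [
        "mean_shortest_path",
        "clustering",
        "modularity",
        "cycles_1",
        "cycles_2",
        "cycles_4",
    ]
    summary = (
        samples.groupby(["model", "mode"])[metrics + ["n_edges"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") for c in summary.columns.to_flat_index()
    ]
    return summary, samples


def run_distance_scan(
    cfg: ExperimentConfig,
    mode: Optional[str] = None,
    distances: Optional[list] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean |flow| versus boundary-species shortest-path distance.

    Returns ``(summary, runs)``: summary has one row per (model, d) with the
    ensemble mean flow magnitude and its standard error.
    """
    mode = mode or cfg.mode
    rows = []
    for model in cfg.models:
        for sample in range(cfg.n_network_samples):
            net = build_network(model, mode, cfg, sample)
            thermo, thermo_seed = attach_thermodynamics(net, cfg, sample)
            path = (cfg.master_seed, _MODEL_INDEX[model], _MODE_INDEX[mode], sample)
            pairs = sample_boundary_pairs(
                substrate_graph(net),
                cfg.pairs_per_distance,
                child_rng(*path, 3),
                distances=distances,
            )
            for p_idx, (b1, b2, d) in enumerate(pairs):
                init_rng = child_rng(*path, 4, p_idx)
                state, _, boundary = simulate_pair(net, thermo, b1, b2, cfg, init_rng)
                sigma_tot, eq_res = total_entropy_check(state, boundary)
                rows.append(
                    {
                        "model": model,
                        "mode": mode,
                        "sample": sample,
                        "network_seed": net.meta["network_seed"],
                        "thermo_seed": thermo_seed,
                        "init_seed": child_seed(*path, 4, p_idx),
                        "b1": b1,
                        "b2": b2,
                        "d": d,
                        "flow": state.boundary_flow,
                        "flow_mag": abs(state.boundary_flow),
                        "sigma_tot": sigma_tot,
                        "eq6_residual": eq_res,
                        "converged": state.converged,
                        "t_final": state.t_final,
                    }
                )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby(["model", "mode", "d"])["flow_mag"]
        .agg(mean_flow="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="count")
        .reset_index()
    )
    return summary, runs


def run_dissipation_ensemble(
    cfg: ExperimentConfig,
    mode: str,
    n_networks: int = 2,
    pairs_per_network: int = 10,
    distance: int = 4,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Pool per-reaction entropy productions at fixed boundary distance.

    For every model, ``n_networks`` networks are generated and
    ``pairs_per_network`` boundary pairs at the given shortest-path distance
    are driven to steady state at (c1, c2).  Returns the pooled sigma
    samples, a per-run record table (flow, Eq.-6 residual, convergence) and
    per-degree normalized dissipation profiles averaged over runs.
    """
    from .analysis import degree_dissipation_profile

    pool = []
    rows = []
    prof_acc: dict[int, list] = {}
    for model in cfg.models:
        for sample in range(n_networks):
            net = build_network(model, mode, cfg, sample)
            thermo, thermo_seed = attach_thermodynamics(net, cfg, sample)
            path = (cfg.master_seed, _MODEL_INDEX[model], _MODE_INDEX[mode], sample)
            pairs = sample_boundary_pairs(
                substrate_graph(net),
                pairs_per_network,
                child_rng(*path, 3),
                distances=[distance],
            )
            for p_idx, (b1, b2, d) in enumerate(pairs):
                init_rng = child_rng(*path, 4, p_idx)
                state, _, boundary = simulate_pair(net, thermo, b1, b2, cfg, init_rng)
                sigma = _safe_sigma(state)
                pool.append(sigma)
                sigma_tot, eq_res = total_entropy_check(state, boundary)
                rows.append(
                    {
                        "model": model,
                        "mode": mode,
                        "sample": sample,
                        "b1": b1,
                        "b2": b2,
                        "d": d,
                        "flow": state.boundary_flow,
                        "flow_mag": abs(state.boundary_flow),
                        "sigma_tot": sigma_tot,
                        "eq6_residual": eq_res,
                        "converged": state.converged,
                    }
                )
                for deg, val in degree_dissipation_profile(net, sigma).items():
                    prof_acc.setdefault(deg, []).append(val)
    profiles = {deg: float(np.mean(vals)) for deg, vals in sorted(prof_acc.items())}
    return np.concatenate(pool), pd.DataFrame(rows), profiles


def run_disequilibrium_ladder(
    cfg: ExperimentConfig, models: Optional[Iterable[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drive nonlinear networks harder by raising c2; track self-organization.

    One nonlinear network per model; for every rung of the c2 ladder, up to
    ``pairs_per_distance`` boundary pairs at the configured distance are
    simulated.  Per run: flow, f_sigma(0.1), sigma_mu / delta_mu and the 2-
    and 4-cycle excess over the random-direction baseline.
    """
    models = tuple(models) if models is not None else cfg.models
    mode = "nonlinear"
    rows = []
    for model in models:
        sample = 0
        net = build_network(model, mode, cfg, sample)
        thermo, thermo_seed = attach_thermodynamics(net, cfg, sample)
        path = (cfg.master_seed, _MODEL_INDEX[model], _MODE_INDEX[mode], sample)
        pairs = sample_boundary_pairs(
            substrate_graph(net),
            cfg.pairs_per_distance,
            child_rng(*path, 3),
            distances=[cfg.ladder_distance],
        )
        for rung, c2 in enumerate(cfg.ladder_c2):
            for p_idx, (b1, b2, d) in enumerate(pairs):
                init_rng = child_rng(*path, 5, rung, p_idx)
                state, thermo_z, boundary = simulate_pair(
                    net, thermo, b1, b2, cfg, init_rng, c2=c2
                )
                sigma = _safe_sigma(state)
                mu = chemical_potentials(
                    thermo_z.mu0, np.maximum(state.x, 1e-300)
                )
                exc = cycle_excess(
                    net,
                    state,
                    reps=cfg.baseline_reps,
                    rng=child_rng(*path, 6, rung, p_idx),
                    lengths=(2, 4),
                )
                try:
                    f_sig = dissipation_fraction(sigma, 0.1)
                except ValueError:
                    f_sig = np.nan
                try:
                    spread = potential_spread(mu, boundary)
                except ValueError:
                    spread = np.nan
                rows.append(
                    {
                        "model": model,
                        "c2": c2,
                        "delta_c": abs(c2 - cfg.c1),
                        "b1": b1,
                        "b2": b2,
                        "d": d,
                        "network_seed": net.meta["network_seed"],
                        "thermo_seed": thermo_seed,
                        "init_seed": child_seed(*path, 5, rung, p_idx),
                        "flow": state.boundary_flow,
                        "flow_mag": abs(state.boundary_flow),
                        "f_sigma_0.1": f_sig,
                        "sigma_mu_norm": spread,
                        "cycle2_excess": exc[2]["excess"],
                        "cycle4_excess": exc[4]["excess"],
                        "converged": state.converged,
                        "t_final": state.t_final,
                    }
                )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby(["model", "c2"])
        .agg(
            mean_flow=("flow_mag", "mean"),
            f_sigma=("f_sigma_0.1", "mean"),
            sigma_mu_norm=("sigma_mu_norm", "mean"),
            cycle2_excess=("cycle2_excess", "mean"),
            cycle4_excess=("cycle4_excess", "mean"),
            n=("flow", "count"),
        )
        .reset_index()
    )
    return summary, runs
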