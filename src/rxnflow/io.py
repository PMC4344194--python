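"""Serialization: graphs (native JSON, GraphML), networks and runs (JSON)."""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

from .dynamics import SteadyState
from .graphs import DirectedMultigraph
from .reactions import Reaction, ReactionNetwork
from .thermo import ThermoAssignment


def graph_to_json(g: DirectedMultigraph, path) -> None:
    payload = {
        "n_nodes": g.n_nodes,
        "edges": g.edges.tolist(),
        "model_tag": g.model_tag,
        "metadata": {
            "ws_ring_degree": g.ws_ring_degree,
            "ps_module": None if g.ps_module is None else g.ps_module.tolist(),
            "ps_height": g.ps_height,
            **{k: v for k, v in g.meta.items() if _jsonable(v)},
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def graph_from_json(path) -> DirectedMultigraph:
    with open(path) as fh:
        d = json.load(fh)
    md = d.get("metadata", {})
    mod = md.get("ps_module")
    return DirectedMultigraph(
        n_nodes=d["n_nodes"],
        edges=np.asarray(d["edges"], dtype=np.int64),
        model_tag=d.get("model_tag", "custom"),
        ws_ring_degree=md.get("ws_ring_degree"),
        ps_module=None if mod is None else np.asarray(mod, dtype=np.int64),
        ps_height=md.get("ps_height"),
        meta={k: v for k, v in md.items()
              if k not in ("ws_ring_degree", "ps_module", "ps_height")},
    )


def graph_to_graphml(g: DirectedMultigraph, path) -> None:
    ig_g = g.to_igraph(directed=True)
    ig_g["model_tag"] = g.model_tag
    ig_g.write_graphml(str(path))


def network_to_json(
    net: ReactionNetwork, path, thermo: Optional[ThermoAssignment] = None
) -> None:
    payload = {
        "n_species": net.n_species,
        "reactions": [
            {"reactants": list(rx.reactants), "products": list(rx.products)}
            for rx in net.reactions
        ],
        "model_tag": net.model_tag,
        "metadata": {
            "ws_ring_degree": net.ws_ring_degree,
            "ps_module": None if net.ps_module is None else net.ps_module.tolist(),
            "ps_height": net.ps_height,
            "ps_level_decay": net.ps_level_decay,
            **{k: v for k, v in net.meta.items() if _jsonable(v)},
        },
    }
    if thermo is not None:
        payload["thermo"] = {
            "mu0": thermo.mu0.tolist(),
            "ea_sampled": thermo.ea_sampled.tolist(),
            "ea_fwd": thermo.ea_fwd.tolist(),
            "ea_bwd": thermo.ea_bwd.tolist(),
            "direction_rule": thermo.direction_rule,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def network_from_json(path):
    """Returns ``(ReactionNetwork, ThermoAssignment | None)``."""
    with open(path) as fh:
        d = json.load(fh)
    md = d.get("metadata", {})
    mod = md.get("ps_module")
    net = ReactionNetwork(
        n_species=d["n_species"],
        reactions=[
            Reaction(tuple(r["reactants"]), tuple(r["products"]))
            for r in d["reactions"]
        ],
        model_tag=d.get("model_tag", "custom"),
        ws_ring_degree=md.get("ws_ring_degree"),
        ps_module=None if mod is None else np.asarray(mod, dtype=np.int64),
        ps_height=md.get("ps_height"),
        ps_level_decay=md.get("ps_level_decay"),
    )
    thermo = None
    if "thermo" in d:
        t = d["thermo"]
        thermo = ThermoAssignment(
            mu0=np.asarray(t["mu0"], dtype=float),
            ea_sampled=np.asarray(t["ea_sampled"], dtype=float),
            ea_fwd=np.asarray(t["ea_fwd"], dtype=float),
            ea_bwd=np.asarray(t["ea_bwd"], dtype=float),
            direction_rule=t.get("direction_rule", "detailed_balance"),
        )
    return net, thermo


def run_to_json(state: SteadyState, path, extra: Optional[dict] = None) -> None:
    payload = {
        "x": state.x.tolist(),
        "v_plus": state.v_plus.tolist(),
        "v_minus": state.v_minus.tolist(),
        "flow": state.boundary_flow,
        "converged": state.converged,
        "t_final": state.t_final,
        "residual": state.residual,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def run_from_json(path) -> SteadyState:
    with open(path) as fh:
        d = json.load(fh)
    return SteadyState(
        x=np.asarray(d["x"], dtype=float),
        v_plus=np.asarray(d["v_plus"], dtype=float),
        v_minus=np.asarray(d["v_minus"], dtype=float),
        boundary_flow=float(d["flow"]),
        converged=bool(d["converged"]),
        t_final=float(d["t_final"]),
        residual=float(d["residual"]),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
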