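"""Reaction networks assembled from directed multigraphs.

Every graph edge becomes a reversible 1<->1 reaction ``X <=> Y`` ("linear"
network).  Nonlinear networks arise by coupling pairs of linear reactions
``A <=> B`` and ``C <=> D`` into a single 2<->2 reaction ``A + C <=> B + D``,
with a pair-selection law chosen so the substrate graph keeps the signature
of the generating network model.  The substrate graph joins two species
whenever some reaction has them on opposite sides; a 1<->1 reaction
contributes one edge and a 2<->2 reaction the four cross pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .graphs import DirectedMultigraph, lowest_common_level

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "linear_network_from_graph",
    "linear_network_from_substrate",
    "coupling_weight",
    "couple_reactions",
    "substrate_edges",
    "substrate_graph",
    "directed_substrate_graph",
    "stoichiometric_matrices",
    "read_reaction_list",
    "write_reaction_list",
]


@dataclass(frozen=True)
class Reaction:
    """A reversible reaction with equal-sized reactant and product multisets."""

    reactants: tuple
    products: tuple

    def __post_init__(self):
        r = tuple(sorted(self.reactants))
        p = tuple(sorted(self.products))
        object.__setattr__(self, "reactants", r)
        object.__setattr__(self, "products", p)
        if len(r) != len(p) or len(r) not in (1, 2):
            raise ValueError("reactions must be 1<->1 or 2<->2")

    @property
    def order(self) -> int:
        return len(self.reactants)

    @property
    def is_linear(self) -> bool:
        return self.order == 1


@dataclass
class ReactionNetwork:
    """Species ``0..n_species-1`` plus an ordered list of reversible reactions."""

    n_species: int
    reactions: list
    model_tag: str = "custom"
    meta: dict = field(default_factory=dict)
    # graph metadata carried over for model-aware coupling
    ws_ring_degree: Optional[int] = None
    ps_module: Optional[np.ndarray] = None
    ps_height: Optional[int] = None
    ps_level_decay: Optional[float] = None

    def __post_init__(self):
        for rx in self.reactions:
            for s in rx.reactants + rx.products:
                if not 0 <= s < self.n_species:
                    raise ValueError("species id outside range")

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def is_linear(self) -> bool:
        return all(rx.is_linear for rx in self.reactions)


def linear_network_from_graph(g: DirectedMultigraph) -> ReactionNetwork:
    """One 1<->1 reaction per edge: reactant = source, product = target."""
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    reactions = [Reaction((int(u),), (int(v),)) for u, v in g.edges]
    return ReactionNetwork(
        g.n_nodes,
        reactions,
        model_tag=g.model_tag,
        ws_ring_degree=g.ws_ring_degree,
        ps_module=g.ps_module,
        ps_height=g.ps_height,
        ps_level_decay=g.meta.get("level_decay"),
        meta=dict(g.meta),
    )


def substrate_edges(net: ReactionNetwork) -> np.ndarray:
    """All (reactant, product) cross pairs, one row per edge instance.

    Rows are oriented reactant -> product in the as-written direction; for a
    2<->2 reaction the four rows appear consecutively.
    """
    rows = []
    for rx in net.reactions:
        for a in rx.reactants:
            for b in rx.products:
                rows.append((a, b))
    return np.array(rows, dtype=np.int64).reshape(-1, 2)


def _reaction_edge_slices(net: ReactionNetwork) -> np.ndarray:
    """Start offset of each reaction's block in :func:`substrate_edges`."""
    sizes = np.array([rx.order ** 2 for rx in net.reactions], dtype=np.int64)
    return np.concatenate([[0], np.cumsum(sizes)])


def substrate_graph(net: ReactionNetwork) -> DirectedMultigraph:
    """The substrate multigraph (use ``directed=False`` exports for topology)."""
    return DirectedMultigraph(
        net.n_species,
        substrate_edges(net),
        model_tag=net.model_tag,
        ws_ring_degree=net.ws_ring_degree,
        ps_module=net.ps_module,
        ps_height=net.ps_height,
    )


def directed_substrate_graph(
    net: ReactionNetwork, net_rates: Sequence[float]
) -> DirectedMultigraph:
    """Substrate graph with every reaction's edges oriented along its net flow.

    Edges run reactant -> product where the net rate is positive and
    product -> reactant where it is negative; a zero rate keeps the
    as-written orientation.
    """
    net_rates = np.asarray(net_rates, dtype=float)
    if net_rates.shape[0] != net.n_reactions:
        raise ValueError("one signed rate per reaction required")
    edges = substrate_edges(net)
    offsets = _reaction_edge_slices(net)
    flip = np.zeros(edges.shape[0], dtype=bool)
    for j, rate in enumerate(net_rates):
        if rate < 0:
            flip[offsets[j] : offsets[j + 1]] = True
    edges[flip] = edges[flip, ::-1]
    return DirectedMultigraph(net.n_species, edges, model_tag=net.model_tag)


def stoichiometric_matrices(net: ReactionNetwork):
    """Return ``(L, R, N)`` as sparse CSR matrices, ``N = R - L``.

    ``L[i, j]``/``R[i, j]`` is the stoichiometric coefficient of species ``i``
    on the left/right of reaction ``j``; duplicated species accumulate
    (``A + A <=> ...`` gives a coefficient of 2).
    """
    rows_l, cols_l, rows_r, cols_r = [], [], [], []
    for j, rx in enumerate(net.reactions):
        for s in rx.reactants:
            rows_l.append(s)
            cols_l.append(j)
        for s in rx.products:
            rows_r.append(s)
            cols_r.append(j)
    shape = (net.n_species, net.n_reactions)
    L = sp.coo_matrix(
        (np.ones(len(rows_l)), (rows_l, cols_l)), shape=shape
    ).tocsr()
    R = sp.coo_matrix(
        (np.ones(len(rows_r)), (rows_r, cols_r)), shape=shape
    ).tocsr()
    L.sum_duplicates()
    R.sum_duplicates()
    return L, R, (R - L).tocsr()


# ---------------------------------------------------------------------------
# coupling


def _ring_distance(u, v, n_nodes):
    d = np.abs(np.asarray(u) - np.asarray(v))
    return np.minimum(d, n_nodes - d)


def coupling_weight(
    model_tag: str,
    pair: tuple,
    net: ReactionNetwork,
    substrate_degree: Optional[np.ndarray] = None,
) -> float:
    """Un-normalized weight for coupling two linear reactions.

    ER: constant 1.  BA: product of the current substrate-graph degrees of
    the two products.  WS: 1 iff both newly introduced substrate edges span a
    ring distance of at most ``k/2``, else 0.  PS: ``p**l1 * p**l2`` for the
    lowest common module levels of the two new edges.
    """
    r1, r2 = pair
    if not (r1.is_linear and r2.is_linear):
        raise ValueError("coupling weights are defined for linear reactions only")
    a, b = r1.reactants[0], r1.products[0]
    c, d = r2.reactants[0], r2.products[0]
    # new substrate edges are (a, d) and (c, b)
    if model_tag == "ER":
        return 1.0
    if model_tag == "BA":
        if substrate_degree is None:
            substrate_degree = _substrate_degrees(net)
        return float(substrate_degree[b] * substrate_degree[d])
    if model_tag == "WS":
        half = net.ws_ring_degree // 2
        n = net.n_species
        ok = _ring_distance(a, d, n) <= half and _ring_distance(c, b, n) <= half
        return 1.0 if ok else 0.0
    if model_tag == "PS":
        p = net.ps_level_decay if net.ps_level_decay is not None else 0.5
        l1 = lowest_common_level(a, d, net.ps_module, net.ps_height)
        l2 = lowest_common_level(c, b, net.ps_module, net.ps_height)
        return float(p ** (l1 + l2))
    raise ValueError(f"unknown model tag {model_tag!r}")


def _substrate_degrees(net: ReactionNetwork) -> np.ndarray:
    deg = np.zeros(net.n_species, dtype=np.int64)
    e = substrate_edges(net)
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    return deg


class CouplingInfeasibleError(RuntimeError):
    """No admissible reaction pair remains for the requested model."""


def couple_reactions(
    net: ReactionNetwork,
    n_couplings: int,
    model_tag: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> ReactionNetwork:
    """Replace ``n_couplings`` pairs of linear reactions by 2<->2 reactions.

    Pairs of distinct, not-yet-used linear reactions are drawn sequentially
    with probability proportional to :func:`coupling_weight`; each draw
    replaces ``A <=> B`` and ``C <=> D`` by ``A + C <=> B + D`` and removes
    both from the pool.  The result keeps the surviving linear reactions (in
    their original order) followed by the coupled reactions in draw order.
    """
    if rng is None:
        rng = np.random.default_rng()
    if model_tag is None:
        model_tag = net.model_tag
    if not net.is_linear:
        raise ValueError("couple_reactions requires a purely linear network")
    m = net.n_reactions
    if 2 * n_couplings > m:
        raise CouplingInfeasibleError(
            f"{model_tag}: {n_couplings} couplings need {2 * n_couplings} linear "
            f"reactions but only {m} exist"
        )

    x = np.array([rx.reactants[0] for rx in net.reactions], dtype=np.int64)
    y = np.array([rx.products[0] for rx in net.reactions], dtype=np.int64)

    if model_tag == "ER":
        chosen = rng.permutation(m)[: 2 * n_couplings]
        pairs = list(zip(chosen[0::2], chosen[1::2]))
    elif model_tag == "BA":
        pairs = _couple_ba(x, y, net.n_species, n_couplings, rng)
    elif model_tag == "WS":
        if net.ws_ring_degree is None:
            raise ValueError("WS coupling requires ring metadata")
        half = net.ws_ring_degree // 2
        w = (
            (_ring_distance(x[:, None], y[None, :], net.n_species) <= half)
            & (_ring_distance(x[None, :], y[:, None], net.n_species) <= half)
        ).astype(np.float64)
        np.fill_diagonal(w, 0.0)
        pairs = _couple_from_table(w, n_couplings, rng, model_tag)
    elif model_tag == "PS":
        if net.ps_module is None:
            raise ValueError("PS coupling requires module metadata")
        p = net.ps_level_decay if net.ps_level_decay is not None else 0.5
        lvl = _pairwise_levels(x, y, net.ps_module)
        b = p ** lvl.astype(np.float64)
        w = b * b.T
        np.fill_diagonal(w, 0.0)
        pairs = _couple_from_table(w, n_couplings, rng, model_tag)
    else:
        raise ValueError(f"unknown model tag {model_tag!r}")

    used = np.zeros(m, dtype=bool)
    nonlinear = []
    for i, j in pairs:
        used[[i, j]] = True
        nonlinear.append(Reaction((int(x[i]), int(x[j])), (int(y[i]), int(y[j]))))
    reactions = [net.reactions[i] for i in range(m) if not used[i]] + nonlinear
    return ReactionNetwork(
        net.n_species,
        reactions,
        model_tag=net.model_tag,
        ws_ring_degree=net.ws_ring_degree,
        ps_module=net.ps_module,
        ps_height=net.ps_height,
        ps_level_decay=net.ps_level_decay,
        meta=dict(net.meta),
    )


def _pairwise_levels(x: np.ndarray, y: np.ndarray, module: np.ndarray) -> np.ndarray:
    """Matrix of lowest common module levels of (x_i, y_j)."""
    bitlen = np.zeros(1 << 16, dtype=np.int16)
    for b in range(1, 17):
        bitlen[1 << (b - 1) : 1 << b] = b
    xor = module[x][:, None] ^ module[y][None, :]
    return bitlen[xor]


def _couple_ba(x, y, n_species, n_couplings, rng):
    """Sequential pair draws with weight deg(product_i) * deg(product_j).

    Degrees are read from the substrate graph as it exists at draw time, so
    edges added by earlier couplings raise the attachment weight of their
    endpoints.  The pair law factorizes, so the first reaction is drawn from
    the exact marginal and the partner from the conditional.
    """
    m = x.shape[0]
    deg = np.zeros(n_species, dtype=np.int64)
    np.add.at(deg, x, 1)
    np.add.at(deg, y, 1)
    alive = np.ones(m, dtype=bool)
    pairs = []
    for _ in range(n_couplings):
        wy = deg[y] * alive
        s = wy.sum()
        marg = wy * (s - wy)
        tot = marg.sum()
        if tot <= 0:
            raise CouplingInfeasibleError("BA: all coupling weights vanished")
        i = int(rng.choice(m, p=marg / tot))
        w2 = wy.astype(np.float64)
        w2[i] = 0.0
        j = int(rng.choice(m, p=w2 / w2.sum()))
        alive[[i, j]] = False
        # new substrate edges (x_i, y_j) and (x_j, y_i)
        np.add.at(deg, [x[i], y[j], x[j], y[i]], 1)
        pairs.append((i, j))
    return pairs


def _couple_from_table(w: np.ndarray, n_couplings: int, rng, model_tag: str):
    """Sequential weighted pair sampling from an explicit symmetric table."""
    m = w.shape[0]
    rowsum = w.sum(axis=1)
    pairs = []
    for _ in range(n_couplings):
        tot = rowsum.sum()
        if tot <= 0:
            raise CouplingInfeasibleError(
                f"{model_tag}: all coupling weights are zero with "
                f"{n_couplings - len(pairs)} couplings outstanding"
            )
        i = int(rng.choice(m, p=np.maximum(rowsum, 0.0) / tot))
        wi = w[i]
        j = int(rng.choice(m, p=wi / wi.sum()))
        # remove both reactions from the pool
        rowsum -= w[:, i] + w[:, j]
        rowsum[[i, j]] = 0.0
        w[[i, j], :] = 0.0
        w[:, [i, j]] = 0.0
        np.maximum(rowsum, 0.0, out=rowsum)
        pairs.append((i, j))
    return pairs


def linear_network_from_substrate(net: ReactionNetwork) -> ReactionNetwork:
    """Linear network with one 1<->1 reaction per substrate edge instance.

    Used to compare nonlinear networks with linear ones on an identical
    substrate topology.
    """
    edges = substrate_edges(net)
    reactions = [Reaction((int(u),), (int(v),)) for u, v in edges]
    return ReactionNetwork(
        net.n_species,
        reactions,
        model_tag=net.model_tag,
        ws_ring_degree=net.ws_ring_degree,
        ps_module=net.ps_module,
        ps_height=net.ps_height,
        meta={**net.meta, "derived_from": "nonlinear_substrate"},
    )


# ---------------------------------------------------------------------------
# plain-text reaction lists


def write_reaction_list(net: ReactionNetwork, path) -> None:
    """Write one reaction per line, e.g. ``a0 + a2 <=> a1 + a3``."""
    with open(path, "w") as fh:
        for rx in net.reactions:
            left = " + ".join(f"s{i}" for i in rx.reactants)
            right = " + ".join(f"s{i}" for i in rx.products)
            fh.write(f"{left} <=> {right}\n")


def read_reaction_list(path, n_species: Optional[int] = None) -> ReactionNetwork:
    """Parse a reaction-list file written by :func:`write_reaction_list`.

    Species tokens may be bare integers or any name; names are mapped to ids
    in order of first appearance (numeric tokens keep their value).
    """
    names: dict[str, int] = {}

    def sid(tok: str) -> int:
        tok = tok.strip()
        body = tok[1:] if tok[:1] in "sS" and tok[1:].isdigit() else tok
        if body.isdigit():
            return int(body)
        if tok not in names:
            names[tok] = len(names)
        return names[tok]

    reactions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            left, right = line.split("<=>")
            reactants = tuple(sid(t) for t in left.split("+"))
            products = tuple(sid(t) for t in right.split("+"))
            reactions.append(Reaction(reactants, products))
    if n_species is None:
        n_species = 1 + max(
            max(rx.reactants + rx.products) for rx in reactions
        )
    return ReactionNetwork(n_species, reactions)
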