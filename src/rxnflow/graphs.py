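"""Random directed multigraph generators.

Four complex-network models produce the substrate topology of the reaction
networks: Erdős–Rényi (ER, uniform), Barabási–Albert (BA, preferential
attachment / scale-free), Watts–Strogatz (WS, rewired ring lattice /
small-world) and Pan–Sinha (PS, hierarchically modular).  All generators
return a :class:`DirectedMultigraph` with *exactly* the requested number of
edges; self-loops and parallel edges are allowed.  Edge orientation is
assigned uniformly at random because the downstream reaction networks need a
direction per reaction while the underlying models are undirected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import igraph as ig
import numpy as np

__all__ = [
    "DirectedMultigraph",
    "generate_er",
    "generate_ba",
    "generate_ws",
    "generate_ps",
    "lowest_common_level",
]


@dataclass
class DirectedMultigraph:
    """A directed multigraph: node set ``0..n_nodes-1`` plus an edge multiset.

    Parameters
    ----------
    n_nodes:
        Number of nodes.
    edges:
        Integer array of shape ``(M, 2)``; row ``(u, v)`` is a directed edge
        ``u -> v``.  Self-loops (``u == v``) and repeated rows are permitted.
    model_tag:
        One of ``{"ER", "BA", "WS", "PS"}`` (or ``"custom"``).
    ws_ring_degree:
        Ring-lattice degree ``k = 2M/N`` (WS only); node ids double as ring
        positions.
    ps_module:
        Per-node elementary-module id in ``[0, 2**ps_height)`` (PS only).
    ps_height:
        Height ``h`` of the binary module tree (PS only).
    meta:
        Free-form provenance (seeds, parameters).
    """

    n_nodes: int
    edges: np.ndarray
    model_tag: str = "custom"
    ws_ring_degree: Optional[int] = None
    ps_module: Optional[np.ndarray] = None
    ps_height: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.edges.size and (
            self.edges.min() < 0 or self.edges.max() >= self.n_nodes
        ):
            raise ValueError("edge endpoint outside [0, n_nodes)")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def self_loop_count(self) -> int:
        """Number of self-loop edge instances (directed 1-cycles)."""
        return int(np.count_nonzero(self.edges[:, 0] == self.edges[:, 1]))

    def to_igraph(self, directed: bool = True) -> ig.Graph:
        """Export to python-igraph, keeping multi-edges and loops."""
        return ig.Graph(
            n=self.n_nodes, edges=[tuple(e) for e in self.edges], directed=directed
        )


def _orient(edges: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip each edge independently with probability 1/2."""
    flip = rng.random(edges.shape[0]) < 0.5
    out = edges.copy()
    out[flip] = out[flip, ::-1]
    return out


def generate_er(
    n_nodes: int, n_edges: int, rng: np.random.Generator
) -> DirectedMultigraph:
    """Erdős–Rényi multigraph: both endpoints of every edge uniform."""
    if n_nodes < 2 or n_edges < 1:
        raise ValueError("need n_nodes >= 2 and n_edges >= 1")
    edges = rng.integers(0, n_nodes, size=(n_edges, 2))
    return DirectedMultigraph(n_nodes, edges, model_tag="ER")


def generate_ba(
    n_nodes: int, n_edges: int, rng: np.random.Generator
) -> DirectedMultigraph:
    """Barabási–Albert multigraph with ``m = round(M/N)`` edges per node.

    Growth starts from a path over the first ``m`` nodes.  Each entering node
    attaches ``m`` edges whose targets are drawn with probability
    proportional to current total degree; the entering node itself is in the
    pool at an initial phantom degree of 1, which permits self-loops.  Edge
    orientation is randomized afterwards, and the edge count is padded or
    trimmed to exactly ``n_edges`` with uniformly chosen extra/removed
    preferential edges.
    """
    if n_nodes < 2 or n_edges < 1:
        raise ValueError("need n_nodes >= 2 and n_edges >= 1")
    m = int(round(n_edges / n_nodes))
    if m < 1:
        raise ValueError("n_edges/n_nodes rounds to zero edges per node")
    if m >= n_nodes:
        raise ValueError("edges per node must be smaller than n_nodes")

    deg = np.zeros(n_nodes, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    # seed core: path over the first m nodes
    for i in range(m - 1):
        edges.append((i, i + 1))
        deg[i] += 1
        deg[i + 1] += 1
    if m == 1:
        # a single seed node has no path edges; give it a phantom presence
        deg[0] = max(deg[0], 0)

    for v in range(m, n_nodes):
        for _ in range(m):
            w = deg[: v + 1].astype(np.float64)
            w[v] = max(deg[v], 1)  # entering node at initial degree >= 1
            if w.sum() <= 0:
                w[:] = 1.0
            t = int(rng.choice(v + 1, p=w / w.sum()))
            edges.append((v, t))
            deg[v] += 1
            deg[t] += 1

    arr = np.array(edges, dtype=np.int64).reshape(-1, 2)
    # pad / trim to exactly n_edges
    while arr.shape[0] < n_edges:
        src = int(rng.integers(n_nodes))
        w = deg.astype(np.float64)
        w[w <= 0] = 1e-12
        t = int(rng.choice(n_nodes, p=w / w.sum()))
        arr = np.vstack([arr, [src, t]])
        deg[src] += 1
        deg[t] += 1
    if arr.shape[0] > n_edges:
        keep = rng.choice(arr.shape[0], size=n_edges, replace=False)
        arr = arr[np.sort(keep)]

    return DirectedMultigraph(n_nodes, _orient(arr, rng), model_tag="BA")


def generate_ws(
    n_nodes: int,
    n_edges: int,
    rewire_fraction: float,
    rng: np.random.Generator,
) -> DirectedMultigraph:
    """Watts–Strogatz multigraph: ring lattice with a rewired fraction.

    ``k = 2 n_edges / n_nodes`` must be a positive even integer; every node is
    joined to its ``k/2`` nearest neighbours on each side of the ring, then
    ``floor(rewire_fraction * M)`` edges (chosen uniformly without
    replacement) have one uniformly chosen endpoint replaced by a uniform
    random node, so rewiring can create self-loops and parallel edges.  Node
    ids are the ring positions.
    """
    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValueError("rewire_fraction must be a probability")
    k2, rem = divmod(2 * n_edges, n_nodes)
    if rem != 0 or k2 % 2 != 0 or k2 == 0:
        raise ValueError("2*n_edges/n_nodes must be a positive even integer")
    half = k2 // 2
    base = np.arange(n_nodes, dtype=np.int64)
    edges = np.concatenate(
        [np.stack([base, (base + d) % n_nodes], axis=1) for d in range(1, half + 1)]
    )
    n_rewire = int(np.floor(rewire_fraction * n_edges))
    if n_rewire:
        which = rng.choice(n_edges, size=n_rewire, replace=False)
        side = rng.integers(0, 2, size=n_rewire)
        edges[which, side] = rng.integers(0, n_nodes, size=n_rewire)
    return DirectedMultigraph(
        n_nodes, _orient(edges, rng), model_tag="WS", ws_ring_degree=k2
    )


def _ps_partition(n_nodes: int, levels: int) -> np.ndarray:
    """Round-robin assignment of nodes to ``2**levels`` elementary modules."""
    return np.arange(n_nodes, dtype=np.int64) % (1 << levels)


def lowest_common_level(u: int, v: int, module: np.ndarray, levels: int) -> int:
    """Lowest binary-tree level at which nodes ``u`` and ``v`` share a module.

    Level 0 means the same elementary module (including ``u == v``); the root
    (level ``levels``) contains every node.  Elementary module ids are laid
    out so that the level-``l`` module of a node is ``module >> l``.
    """
    module = np.asarray(module)
    n = module.shape[0]
    if not (0 <= u < n and 0 <= v < n):
        raise ValueError("node outside partition")
    x = int(module[u]) ^ int(module[v])
    return x.bit_length()


def generate_ps(
    n_nodes: int,
    n_edges: int,
    level_decay: float,
    levels: int,
    rng: np.random.Generator,
) -> DirectedMultigraph:
    """Pan–Sinha hierarchically modular multigraph.

    Nodes are partitioned round-robin into ``2**levels`` elementary modules
    of near-equal size, arranged as leaves of a binary tree of height
    ``levels``.  Each edge is drawn by sampling an unordered node pair
    ``{u, v}`` (``u == v`` allowed) with weight ``p**l(u, v)`` where ``l`` is
    the lowest common module level, then orienting it uniformly at random.
    """
    if not 0.0 < level_decay <= 1.0:
        raise ValueError("level_decay must be in (0, 1]")
    if (1 << levels) > n_nodes:
        raise ValueError("2**levels exceeds n_nodes")
    module = _ps_partition(n_nodes, levels)
    n_mod = 1 << levels
    nodes_by_module = [np.flatnonzero(module == m) for m in range(n_mod)]
    sizes = np.array([len(a) for a in nodes_by_module], dtype=np.int64)

    # pair counts per level: level 0 = unordered pairs (with repetition)
    # inside one elementary module; level l>=1 = cross pairs between the two
    # level-(l-1) children of each level-l module.
    level_module_counts: list[np.ndarray] = [sizes * (sizes + 1) // 2]
    sub_sizes = sizes.copy()
    for l in range(1, levels + 1):
        left, right = sub_sizes[0::2], sub_sizes[1::2]
        level_module_counts.append(left * right)
        sub_sizes = left + right
    level_totals = np.array([c.sum() for c in level_module_counts], dtype=np.float64)
    level_weights = level_totals * level_decay ** np.arange(levels + 1)
    level_p = level_weights / level_weights.sum()

    # members[l][q] = nodes whose level-l module is q
    members: list[list[np.ndarray]] = [nodes_by_module]
    for l in range(1, levels + 1):
        prev = members[-1]
        members.append(
            [np.concatenate([prev[2 * q], prev[2 * q + 1]]) for q in range(len(prev) // 2)]
        )

    edges = np.empty((n_edges, 2), dtype=np.int64)
    lvl = rng.choice(levels + 1, size=n_edges, p=level_p)
    for e in range(n_edges):
        l = int(lvl[e])
        counts = level_module_counts[l].astype(np.float64)
        q = int(rng.choice(counts.shape[0], p=counts / counts.sum()))
        if l == 0:
            nodes = nodes_by_module[q]
            s = len(nodes)
            t = int(rng.integers(s * (s + 1) // 2))
            # unrank unordered pair (i <= j) from a triangular index
            i = 0
            while t >= s - i:
                t -= s - i
                i += 1
            u, v = int(nodes[i]), int(nodes[i + t])
        else:
            left_members = members[l - 1][2 * q]
            right_members = members[l - 1][2 * q + 1]
            u = int(left_members[rng.integers(len(left_members))])
            v = int(right_members[rng.integers(len(right_members))])
        edges[e] = (u, v)
    return DirectedMultigraph(
        n_nodes,
        _orient(edges, rng),
        model_tag="PS",
        ps_module=module,
        ps_height=levels,
        meta={"level_decay": float(level_decay)},
    )
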