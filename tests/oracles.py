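"""Independent reference implementations used only by the test suite."""

import numpy as np
from scipy import integrate

from rxnflow.graphs import DirectedMultigraph
from rxnflow.thermo import planck_like_pdf


def brute_force_cycles(g: DirectedMultigraph, length: int) -> int:
    """Depth-limited DFS over edge instances; one count per rotation class."""
    if length == 1:
        return int(sum(1 for u, v in g.edges if u == v))
    edges = [tuple(e) for e in g.edges]
    if length == 2:
        count = 0
        for i in range(len(edges)):
            u1, v1 = edges[i]
            if u1 == v1:
                continue
            for j in range(i + 1, len(edges)):
                if edges[j] == (v1, u1):
                    count += 1
        return count
    assert length == 4
    out = {}
    for idx, (u, v) in enumerate(edges):
        out.setdefault(u, []).append((v, idx))
    total = 0
    for i, (a, b) in enumerate(edges):
        if a == b:
            continue
        for c, j in out.get(b, ()):
            if j == i or c in (a, b):
                continue
            for d, k in out.get(c, ()):
                if k in (i, j) or d in (a, b, c):
                    continue
                for e, l in out.get(d, ()):
                    if e == a and l not in (i, j, k):
                        total += 1
    assert total % 4 == 0
    return total // 4


def planck_cdf_oracle():
    """Quadrature CDF of the activation-energy law on a log grid."""
    grid = np.logspace(-2, 5, 400)
    cdf = np.empty_like(grid)
    acc = 0.0
    prev = 0.0
    for i, g in enumerate(grid):
        piece, _ = integrate.quad(planck_like_pdf, prev, g, limit=200)
        acc += piece
        cdf[i] = acc
        prev = g
    return grid, np.clip(cdf, 0, 1)
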