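"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: quaternion (Horn)
superposition instead of SVD/Kabsch, exhaustive path enumeration instead of
Brandes accumulation, and exhaustive partition search instead of divisive
community detection.
"""

from itertools import permutations

import networkx as nx
import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    sxx, sxy, sxz = (p[:, 0] * q[:, 0]).sum(), (p[:, 0] * q[:, 1]).sum(), (p[:, 0] * q[:, 2]).sum()
    syx, syy, syz = (p[:, 1] * q[:, 0]).sum(), (p[:, 1] * q[:, 1]).sum(), (p[:, 1] * q[:, 2]).sum()
    szx, szy, szz = (p[:, 2] * q[:, 0]).sum(), (p[:, 2] * q[:, 1]).sum(), (p[:, 2] * q[:, 2]).sum()
    K = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = p.shape[0]
    msd = (np.sum(p**2) + np.sum(q**2) - 2.0 * lam_max) / n
    return float(np.sqrt(max(msd, 0.0)))


def _all_shortest_paths(g: nx.Graph, s, t):
    """All minimum-total-weight simple paths between s and t (enumeration)."""
    best, paths = np.inf, []
    for path in nx.all_simple_paths(g, s, t):
        w = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        if w < best - 1e-12:
            best, paths = w, [path]
        elif abs(w - best) <= 1e-12:
            paths.append(path)
    return paths


def brute_force_betweenness(g: nx.Graph):
    """Node and edge betweenness by explicit shortest-path enumeration."""
    node_bt = {n: 0.0 for n in g.nodes}
    edge_bt = {tuple(sorted(e)): 0.0 for e in g.edges}
    nodes = list(g.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            paths = _all_shortest_paths(g, s, t)
            share = 1.0 / len(paths)
            for path in paths:
                for n in path[1:-1]:
                    node_bt[n] += share
                for u, v in zip(path, path[1:]):
                    edge_bt[tuple(sorted((u, v)))] += share
    return node_bt, edge_bt


def _partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_max_modularity(g: nx.Graph):
    """The partition maximising Newman–Girvan modularity, by full search.

    Only feasible for graphs of ≲10 nodes; restrict the search to partitions
    whose blocks are connected (any modularity-maximal block is connected in
    a connected graph with positive modularity).
    """
    best_q, best = -np.inf, None
    for part in _partitions(list(g.nodes)):
        blocks = [set(b) for b in part]
        if any(not nx.is_connected(g.subgraph(b)) for b in blocks):
            continue
        q = nx.algorithms.community.modularity(g, blocks, weight=None)
        if q > best_q:
            best_q, best = q, blocks
    return best, best_q


def two_sphere_buried_area(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Exact buried spherical-cap areas of two intersecting spheres.

    Returns (buried_on_1, buried_on_2) for spheres of radii r1, r2 at centre
    distance d (0 < d < r1 + r2, neither engulfed).
    """
    # plane of intersection at distance x1 from centre 1
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    x2 = d - x1
    cap1 = 2.0 * np.pi * r1 * (r1 - x1)
    cap2 = 2.0 * np.pi * r2 * (r2 - x2)
    return float(cap1), float(cap2)
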