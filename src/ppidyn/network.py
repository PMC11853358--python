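"""Correlation-weighted residue interaction network and community analysis.

Residues (anchored on their Cα atoms) are nodes; an edge joins two residues
whose atoms stay within a contact cutoff (4.5 Å) for at least a persistence
fraction (0.75) of the analysis frames. Edge length is d_ij = −log|C_ij|
(|C| floored at 1e-6), so strongly correlated residues are "close".

Communities come from the Girvan–Newman divisive algorithm — iteratively
removing the edge with maximal weighted shortest-path betweenness — keeping
the partition of maximal Newman–Girvan modularity; communities smaller than a
minimum size are omitted from the report (membership is still recorded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import networkx as nx
import numpy as np

from ppidyn.correlation import CorrelationMatrix
from ppidyn.interactions import contact_occupancy
from ppidyn.structio import TrajectoryEnsemble

__all__ = [
    "ResidueGraph",
    "CommunityPartition",
    "build_network",
    "girvan_newman",
    "betweenness",
    "intercommunity_strength",
]

CORRELATION_FLOOR = 1e-6


@dataclass
class ResidueGraph:
    """Undirected residue graph; node ids are ``chain:resnum`` labels.

    Each edge carries ``weight`` (= −log|C|), ``abs_corr`` and
    ``persistence`` attributes.
    """

    graph: nx.Graph
    correlation_floor: float = CORRELATION_FLOOR

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CommunityPartition:
    """Community id per node plus the modularity of the kept partition.

    ``communities`` lists every block of the partition; ``reported`` lists
    only those meeting the minimum-size rule, re-indexed 0..k−1.
    """

    membership: dict[str, int]
    communities: list[set[str]]
    reported: list[set[str]]
    modularity: float
    min_size: int


def build_network(
    traj: TrajectoryEnsemble,
    dccm_matrix: CorrelationMatrix,
    cutoff: float = 4.5,
    persistence: float = 0.75,
    contact_mode: str = "heavy-any",
) -> ResidueGraph:
    """Build the persistence-filtered, correlation-weighted residue graph.

    An edge exists iff the residue pair stays within ``cutoff`` for at least
    ``persistence`` of the analysis frames (inclusive). The contact test uses
    any-heavy-atom minimum distances by default; ``contact_mode='ca'`` is a
    stricter Cα–Cα variant for sensitivity checks.
    """
    labels = dccm_matrix.residue_labels
    traj_labels = [
        f"{a.chain_id}:{a.residue_number}"
        for a in traj.topology.atoms if a.atom_name == "CA"
    ]
    if labels != traj_labels:
        raise ValueError("DCCM residue labels do not match trajectory residues")
    pos = {lab: i for i, lab in enumerate(labels)}
    g = nx.Graph()
    for lab in labels:
        g.add_node(lab)
    records = contact_occupancy(traj, cutoff=cutoff, mode=contact_mode)
    for r in records:
        if r.occupancy < persistence:
            continue
        la = f"{r.chain_a}:{r.resnum_a}"
        lb = f"{r.chain_b}:{r.resnum_b}"
        if la not in pos or lb not in pos or la == lb:
            continue
        cval = dccm_matrix.C[pos[la], pos[lb]]
        absc = CORRELATION_FLOOR if np.isnan(cval) else max(abs(float(cval)), CORRELATION_FLOOR)
        g.add_edge(
            la, lb,
            weight=-math.log(absc),
            abs_corr=absc,
            persistence=r.occupancy,
        )
    return ResidueGraph(graph=g)


def betweenness(graph: ResidueGraph | nx.Graph) -> tuple[dict, dict]:
    """Weighted shortest-path betweenness for nodes and edges.

    Path lengths are sums of edge weights d_ij; ties split equally among
    shortest paths (Brandes accumulation). Values are unnormalised pair
    dependencies.
    """
    g = graph.graph if isinstance(graph, ResidueGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    node_bt = nx.betweenness_centrality(g, weight="weight", normalized=False)
    edge_bt = nx.edge_betweenness_centrality(g, weight="weight", normalized=False)
    return node_bt, edge_bt


def _modularity(g_full: nx.Graph, communities: list[set]) -> float:
    """Newman–Girvan modularity of a partition on the original (unweighted)
    edge structure."""
    return nx.algorithms.community.modularity(g_full, communities, weight=None)


def _component_edge_betweenness(g: nx.Graph, nodes: set) -> dict:
    sub = g.subgraph(nodes)
    return nx.edge_betweenness_centrality(sub, weight="weight", normalized=False)


def girvan_newman(
    graph: ResidueGraph | nx.Graph,
    min_size: int = 3,
    max_communities: int | None = None,
) -> CommunityPartition:
    """Girvan–Newman divisive communities, kept at maximum modularity.

    Edges are removed in order of maximal weighted edge betweenness (only the
    component containing the removed edge is rescored, which is exact); after
    each connectivity change the partition into connected components is
    scored by modularity against the original graph, and the best-scoring
    partition wins. The divisive sequence stops once ``max_communities``
    components exist (the modularity peak sits far earlier for any modular
    graph). Components smaller than ``min_size`` are excluded from the
    reported communities (membership is retained).
    """
    g_full = (graph.graph if isinstance(graph, ResidueGraph) else graph).copy()
    if g_full.number_of_nodes() == 0:
        raise ValueError("empty graph")
    work = g_full.copy()

    comps = [set(c) for c in nx.connected_components(work)]
    best = [set(c) for c in comps]
    best_q = _modularity(g_full, best) if g_full.number_of_edges() else 0.0
    n_comp = len(comps)
    edge_bt: dict = {}
    for c in comps:
        edge_bt.update(_component_edge_betweenness(work, c))
    while work.number_of_edges() > 0:
        if max_communities is not None and n_comp >= max_communities:
            break
        # deterministic tie-break: lexicographic on stringified endpoints
        edge = max(
            sorted(edge_bt, key=lambda e: (str(e[0]), str(e[1]))),
            key=lambda e: edge_bt[e],
        )
        u, v = edge
        affected = nx.node_connected_component(work, u)
        work.remove_edge(u, v)
        for e in list(edge_bt):
            if e[0] in affected:
                del edge_bt[e]
        pieces = [set(c) for c in nx.connected_components(work.subgraph(affected))]
        for c in pieces:
            edge_bt.update(_component_edge_betweenness(work, c))
        if len(pieces) > 1:
            n_comp += 1
            comps = [c for c in comps if c != affected] + pieces
            q = _modularity(g_full, comps)
            if q > best_q + 1e-12:
                best_q = q
                best = [set(c) for c in comps]
    best = sorted(best, key=lambda c: (-len(c), sorted(c)[0]))
    membership = {n: i for i, c in enumerate(best) for n in c}
    reported = [c for c in best if len(c) >= min_size]
    return CommunityPartition(
        membership=membership,
        communities=best,
        reported=reported,
        modularity=best_q,
        min_size=min_size,
    )


def intercommunity_strength(
    graph: ResidueGraph | nx.Graph,
    partition: CommunityPartition,
) -> dict[tuple[int, int], float]:
    """Coupling strength between community pairs: Σ |C_ij| over crossing edges.

    Only nonzero pairs are returned. The |C| convention (not −log|C|) makes
    larger values mean stronger intercommunity coupling.
    """
    g = graph.graph if isinstance(graph, ResidueGraph) else graph
    missing = [n for n in g.nodes if n not in partition.membership]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    out: dict[tuple[int, int], float] = {}
    for u, v, data in g.edges(data=True):
        cu, cv = partition.membership[u], partition.membership[v]
        if cu == cv:
            continue
        key = (min(cu, cv), max(cu, cv))
        out[key] = out.get(key, 0.0) + float(data.get("abs_corr", math.exp(-data["weight"])))
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_edge_list(graph: ResidueGraph, path: str | Path) -> None:
    g = graph.graph
    with open(path, "w") as fh:
        fh.write("resA\tresB\tweight\tabsC\tpersistence\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{d['weight']:.6f}\t{d['abs_corr']:.6f}\t{d['persistence']:.6f}\n"
            )


def write_graphml(graph: ResidueGraph, path: str | Path) -> None:
    nx.write_graphml(graph.graph, path)


def write_communities_tsv(partition: CommunityPartition, path: str | Path) -> None:
    reported_ids = {id(c) for c in partition.reported}
    with open(path, "w") as fh:
        fh.write(f"# modularity={partition.modularity:.6f} min_size={partition.min_size}\n")
        fh.write("node\tcommunity\treported\n")
        for i, c in enumerate(partition.communities):
            rep = int(len(c) >= partition.min_size)
            for n in sorted(c):
                fh.write(f"{n}\t{i}\t{rep}\n")


def write_coupling_tsv(strengths: dict[tuple[int, int], float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("communityA\tcommunityB\tstrength_absC\n")
        for (a, b), s in sorted(strengths.items()):
            fh.write(f"{a}\t{b}\t{s:.6f}\n")
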