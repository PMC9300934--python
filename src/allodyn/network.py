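"""Occupancy-gated, correlation-weighted residue interaction networks.

Residues are nodes; two residues are connected iff they sit within a contact
cutoff (default 4.5 A, minimum heavy-atom distance) in at least a minimum
fraction of frames (default 75%), excluding trivial sequence neighbours.
Each surviving edge is weighted d_ij = -log|C_ij| with C_ij the dynamic
cross-correlation, so strongly correlated pairs are "short" and weighted
shortest paths trace chains of correlated motion.  On this graph we compute
Girvan-Newman communities cut at maximum modularity, inter-community
connectivity (shortest-path crossing counts), and optimal/suboptimal
source->target paths via Floyd-Warshall with deterministic tie-breaking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .correlation import CorrelationMatrix
from .errors import AnalysisError
from .trajectory import Ensemble, resolve_selection

__all__ = [
    "ContactMap",
    "CommunityPartition",
    "PathResult",
    "contact_occupancy",
    "weight_edges",
    "detect_communities",
    "intercommunity_connectivity",
    "floyd_warshall",
    "optimal_path",
    "suboptimal_paths",
]

Node = tuple[str, int]  # (chain_id, residue_id)


@dataclass
class ContactMap:
    """Residue-pair contact occupancy and the gated adjacency."""

    nodes: list[Node]
    occupancy: np.ndarray  # R x R fraction of frames in contact
    adjacency: np.ndarray  # R x R bool, gated by min_occupancy and exclusion
    cutoff: float
    min_occupancy: float
    contact_mode: str
    neighbor_exclusion: int


@dataclass
class CommunityPartition:
    labels: dict[Node, int]
    modularity: float
    connectivity: dict[tuple[int, int], int] = field(default_factory=dict)

    def communities(self) -> list[list[Node]]:
        out: dict[int, list[Node]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, []).append(node)
        return [sorted(out[k]) for k in sorted(out)]


@dataclass
class PathResult:
    nodes: list[Node]
    length: float
    reachable: bool = True

    @property
    def length_x100(self) -> int:
        """Scaled-integer length convention (raw weighted length x 100, rounded)."""
        return int(round(self.length * 100)) if self.reachable else -1

    @property
    def n_residues(self) -> int:
        return len(self.nodes)


def contact_occupancy(
    ensemble: Ensemble,
    node_selection: str = "chain A",
    cutoff: float = 4.5,
    min_occupancy: float = 0.75,
    contact_mode: str = "heavy",
    neighbor_exclusion: int = 1,
    chunk: int = 500,
) -> ContactMap:
    """Fraction of frames each residue pair is in contact, and the gated graph.

    ``contact_mode='heavy'`` (default) uses the minimum distance over the
    residues' non-hydrogen atoms; ``'ca'`` uses C-alpha distance.  Sequence
    neighbours with |i - j| <= neighbor_exclusion on the same chain are never
    edges.  Occupancy is counted with an inclusive cutoff.
    """
    idx = resolve_selection(ensemble, node_selection)
    atoms = ensemble.topology.atoms
    if contact_mode == "ca":
        idx = np.asarray([i for i in idx if atoms[i].name == "CA"], int)
    elif contact_mode == "heavy":
        idx = np.asarray([i for i in idx if atoms[i].element.upper() != "H"], int)
    else:
        raise AnalysisError(f"unknown contact mode {contact_mode!r}")
    if idx.size == 0:
        raise AnalysisError("node selection resolves to no atoms")

    nodes: list[Node] = []
    starts = []
    for pos, i in enumerate(idx):
        key = (atoms[i].chain_id, atoms[i].residue_id)
        if not nodes or nodes[-1] != key:
            if key in nodes:
                raise AnalysisError(f"residue {key} atoms not contiguous in selection")
            nodes.append(key)
            starts.append(pos)
    starts = np.asarray(starts, int)
    r = len(nodes)

    count = np.zeros((r, r))
    for lo in range(0, ensemble.n_frames, chunk):
        xyz = ensemble.frames[lo : lo + chunk][:, idx, :]
        d = np.linalg.norm(xyz[:, :, None, :] - xyz[:, None, :, :], axis=3)
        d = np.minimum.reduceat(d, starts, axis=1)
        d = np.minimum.reduceat(d, starts, axis=2)
        count += (d <= cutoff).sum(axis=0)
    occupancy = count / ensemble.n_frames

    adjacency = occupancy >= min_occupancy
    np.fill_diagonal(adjacency, False)
    for i in range(r):
        for j in range(r):
            if nodes[i][0] == nodes[j][0] and abs(nodes[i][1] - nodes[j][1]) <= neighbor_exclusion:
                adjacency[i, j] = False
    return ContactMap(nodes, occupancy, adjacency, cutoff, min_occupancy, contact_mode, neighbor_exclusion)


def weight_edges(
    contacts: ContactMap, corr: CorrelationMatrix, log_base: str = "e"
) -> nx.Graph:
    """Build the weighted residue graph: d_ij = -log|C_ij| on contact edges.

    Edges whose correlation is masked (zero-variance node) or exactly 0 are
    dropped (infinite information distance), with a warning for masked ones.
    """
    log = math.log if log_base == "e" else (math.log10 if log_base == "10" else None)
    if log is None:
        raise AnalysisError(f"log base must be 'e' or '10', got {log_base!r}")
    corr_index = {key: k for k, key in enumerate(corr.residue_ids)}
    missing = [n for n in contacts.nodes if n not in corr_index]
    if missing:
        raise AnalysisError(f"nodes missing from correlation matrix: {missing[:5]}")
    g = nx.Graph(log_base=log_base)
    g.add_nodes_from(sorted(contacts.nodes))
    r = len(contacts.nodes)
    dropped_masked = 0
    for i in range(r):
        for j in range(i + 1, r):
            if not contacts.adjacency[i, j]:
                continue
            u, v = contacts.nodes[i], contacts.nodes[j]
            c = corr.matrix[corr_index[u], corr_index[v]]
            if np.isnan(c):
                dropped_masked += 1
                continue
            absc = abs(float(c))
            if absc == 0.0:
                continue
            g.add_edge(u, v, occupancy=float(contacts.occupancy[i, j]), absC=absc,
                       weight=0.0 if absc >= 1.0 else -log(absc))
    if dropped_masked:
        warnings.warn(f"{dropped_masked} contact edges dropped: masked correlations")
    return g


def _components_partition(g: nx.Graph) -> list[frozenset]:
    return sorted((frozenset(c) for c in nx.connected_components(g)), key=lambda c: sorted(c)[0])


def detect_communities(graph: nx.Graph) -> CommunityPartition:
    """Girvan-Newman hierarchy cut at maximum modularity.

    Edge betweenness uses the -log|C| weights as distances; modularity uses
    |C| as the affinity weight.  Ties (in betweenness and in modularity) are
    broken lexicographically / toward fewer communities, so the result is
    deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise AnalysisError("empty network")
    work = graph.copy()
    candidates = [_components_partition(work)]
    while work.number_of_edges() > 0:
        betw = nx.edge_betweenness_centrality(work, weight="weight")
        # deterministic: highest betweenness, then lexicographically smallest edge
        top = max(betw.values())
        tied = sorted(e for e, v in betw.items() if abs(v - top) < 1e-12)
        work.remove_edge(*tied[0])
        part = _components_partition(work)
        if len(part) > len(candidates[-1]):
            candidates.append(part)
    best_part = None
    best_q = -np.inf
    for part in candidates:
        q = nx.algorithms.community.modularity(graph, part, weight="absC") if graph.number_of_edges() else 0.0
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    labels: dict[Node, int] = {}
    for lab, comm in enumerate(sorted(best_part, key=lambda c: sorted(c)[0])):
        for node in sorted(comm):
            labels[node] = lab
    return CommunityPartition(labels=labels, modularity=float(best_q))


def floyd_warshall(graph: nx.Graph) -> tuple[list[Node], np.ndarray, np.ndarray]:
    """All-pairs shortest paths with path reconstruction.

    Returns (sorted node list, distance matrix, next-hop matrix).  Updates
    only on strict improvement with intermediates scanned in sorted order,
    so reconstructed paths are deterministic.
    """
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    nxt = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        nxt[i, i] = i
    for u, v, data in graph.edges(data=True):
        i, j = index[u], index[v]
        w = float(data["weight"])
        if w < dist[i, j]:
            dist[i, j] = dist[j, i] = w
            nxt[i, j] = j
            nxt[j, i] = i
    for k in range(n):
        for i in range(n):
            dik = dist[i, k]
            if not np.isfinite(dik):
                continue
            better = dik + dist[k] < dist[i] - 1e-15
            dist[i, better] = dik + dist[k, better]
            nxt[i, better] = nxt[i, k]
    return nodes, dist, nxt


def _lookup(graph: nx.Graph, residue: Node | int) -> Node:
    if isinstance(residue, tuple):
        if residue not in graph:
            raise AnalysisError(f"residue {residue} not in network")
        return residue
    hits = [n for n in graph.nodes if n[1] == residue]
    if len(hits) != 1:
        raise AnalysisError(f"residue id {residue} matches {len(hits)} network nodes")
    return hits[0]


def optimal_path(graph: nx.Graph, source: Node | int, target: Node | int) -> PathResult:
    """Minimum-total-weight source->target path (Floyd-Warshall).

    A disconnected pair yields an unreachable PathResult, not an exception.
    """
    s, t = _lookup(graph, source), _lookup(graph, target)
    nodes, dist, nxt = floyd_warshall(graph)
    index = {n: i for i, n in enumerate(nodes)}
    i, j = index[s], index[t]
    if not np.isfinite(dist[i, j]):
        return PathResult(nodes=[], length=math.inf, reachable=False)
    path = [s]
    while i != j:
        i = int(nxt[i, j])
        path.append(nodes[i])
    return PathResult(nodes=path, length=float(dist[index[s], j]))


def suboptimal_paths(
    graph: nx.Graph,
    source: Node | int,
    target: Node | int,
    delta: float = 0.20,
    max_k: int | None = None,
) -> list[PathResult]:
    """All simple paths within ``delta`` of the optimal length, sorted.

    ``delta`` is in raw weight units (0.20 corresponds to 20 in the
    x100 scaled-integer convention).  Sorted by length then lexicographic
    node sequence; optionally truncated to the first ``max_k``.
    """
    s, t = _lookup(graph, source), _lookup(graph, target)
    best = optimal_path(graph, s, t)
    if not best.reachable:
        return []
    bound = best.length + delta + 1e-12
    # lower bounds to target for pruning
    dist_to_t = nx.single_source_dijkstra_path_length(graph, t, weight="weight")
    results: list[PathResult] = []
    path: list[Node] = [s]
    on_path = {s}

    def dfs(u: Node, acc: float) -> None:
        if u == t:
            results.append(PathResult(nodes=list(path), length=acc))
            return
        for v in sorted(graph.neighbors(u)):
            if v in on_path:
                continue
            w = acc + graph[u][v]["weight"]
            if v not in dist_to_t or w + dist_to_t[v] > bound:
                continue
            path.append(v)
            on_path.add(v)
            dfs(v, w)
            path.pop()
            on_path.remove(v)

    dfs(s, 0.0)
    results.sort(key=lambda p: (p.length, p.nodes))
    return results[:max_k] if max_k is not None else results


def intercommunity_connectivity(
    graph: nx.Graph, partition: CommunityPartition
) -> dict[tuple[int, int], int]:
    """Shortest-path crossing counts per community pair.

    For every unordered node pair, the (deterministic) Floyd-Warshall
    shortest path is walked; every traversed edge joining two communities
    increments that community pair's count.  Symmetric by construction.
    """
    nodes, dist, nxt = floyd_warshall(graph)
    index = {n: i for i, n in enumerate(nodes)}
    counts: dict[tuple[int, int], int] = {}
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isfinite(dist[i, j]):
                continue
            a = i
            while a != j:
                b = int(nxt[a, j])
                pa = partition.labels[nodes[a]]
                pb = partition.labels[nodes[b]]
                if pa != pb:
                    key = (min(pa, pb), max(pa, pb))
                    counts[key] = counts.get(key, 0) + 1
                a = b
    return counts
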