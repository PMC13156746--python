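"""Dynamical cross-correlation networks and allostery analysis.

Residues (alpha-carbon nodes) are connected when their heavy atoms stay
within a contact cutoff for a minimum fraction of frames, excluding
immediate sequence neighbors; each contact edge is weighted by
w = −log|C| where C is the normalized cross-correlation of residue
fluctuations, so strongly correlated residues are "close" for shortest
path purposes.  On this graph the module computes Girvan–Newman
communities, weighted edge betweenness (ordered-pair counting,
unnormalized so absolute thresholds are meaningful at ~375 nodes),
critical inter-community elements, weighted shortest/suboptimal paths,
and unique-edge differences between two systems.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from actintools.ensemble import _iterative_mean_fit
from actintools.model_io import ProtomerView, Trajectory

__all__ = [
    "NetworkParams",
    "DynamicNetwork",
    "CommunityPartition",
    "PathResult",
    "dccm",
    "contact_map",
    "build_network",
    "girvan_newman",
    "edge_betweenness",
    "critical_elements",
    "suboptimal_paths",
    "network_difference",
]

ResidueKey = tuple[str, int]


@dataclass
class NetworkParams:
    """Contact/weighting conventions, every one configurable.

    Defaults: 4.5 Å heavy-atom contact distance, 75% frame occupancy,
    |i−j| ≤ 1 sequence-neighbor exclusion, edge weight −log|C_ij|.
    """

    contact_cutoff_A: float = 4.5
    occupancy_min: float = 0.75
    exclude_neighbors: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.occupancy_min <= 1):
            raise ValueError("occupancy_min must be in (0, 1]")
        if self.contact_cutoff_A <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass
class DynamicNetwork:
    nodes: list[ResidueKey]
    correlation: np.ndarray
    contacts: np.ndarray
    graph: nx.Graph
    params: NetworkParams = field(default_factory=NetworkParams)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class CommunityPartition:
    communities: list[set[ResidueKey]]
    membership: dict[ResidueKey, int]
    modularity: float
    critical_nodes: list[ResidueKey] = field(default_factory=list)
    critical_edges: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (-0.5 - 1e-9 <= self.modularity <= 1.0 + 1e-9):
            raise ValueError("modularity out of range")


@dataclass
class PathResult:
    source: ResidueKey
    target: ResidueKey
    nodes: list[ResidueKey]
    total_weight: float
    exists: bool = True

    @property
    def intermediates(self) -> list[ResidueKey]:
        return self.nodes[1:-1] if self.exists else []

    @property
    def intermediate_count(self) -> int:
        return len(self.intermediates)


# ---------------------------------------------------------------------------
# Correlation and contacts
# ---------------------------------------------------------------------------


def dccm(
    traj: Trajectory | np.ndarray, ca_indices: np.ndarray
) -> np.ndarray:
    """Dynamical cross-correlation matrix of alpha-carbon fluctuations.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) over frames,
    after iterative superposition to the mean.  Zero-variance nodes get
    NaN rows/columns (flagged missing, not zero).
    """
    frames = traj.frames if isinstance(traj, Trajectory) else np.asarray(traj)
    ca = np.asarray(ca_indices)
    fitted = _iterative_mean_fit(frames, ca, iterations=2)
    pos = fitted[:, ca, :]
    delta = pos - pos.mean(axis=0)
    cov = np.einsum("fid,fjd->ij", delta, delta) / frames.shape[0]
    var = np.diag(cov).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        c = cov / np.sqrt(np.outer(var, var))
    c[var == 0, :] = np.nan
    c[:, var == 0] = np.nan
    good = var > 0
    c[np.ix_(good, good)] = np.clip(c[np.ix_(good, good)], -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def contact_map(
    traj: Trajectory | np.ndarray,
    view_or_groups: ProtomerView | Sequence[Sequence[int]],
    params: NetworkParams | None = None,
) -> np.ndarray:
    """Boolean residue-contact matrix.

    Edge (i, j) iff the minimum heavy-atom distance is within the cutoff
    in at least ``occupancy_min`` of frames and |i−j| exceeds the
    sequence-neighbor exclusion.
    """
    params = params or NetworkParams()
    frames = traj.frames if isinstance(traj, Trajectory) else np.asarray(traj)
    if isinstance(view_or_groups, ProtomerView):
        groups = [
            np.asarray(view_or_groups.heavy_indices[n])
            for n in view_or_groups.residue_numbers
        ]
    else:
        groups = [np.asarray(g) for g in view_or_groups]
    n = len(groups)
    n_frames = frames.shape[0]
    hits = np.zeros((n, n), dtype=int)
    single = all(len(g) == 1 for g in groups)
    if single:
        idx = np.array([g[0] for g in groups])
        for f in range(n_frames):
            pts = frames[f][idx]
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
            hits += d2 <= params.contact_cutoff_A**2
    else:
        cut2 = params.contact_cutoff_A**2
        for f in range(n_frames):
            coords = frames[f]
            pts = [coords[g] for g in groups]
            for i in range(n):
                for j in range(i + 1, n):
                    d2 = np.sum(
                        (pts[i][:, None, :] - pts[j][None, :, :]) ** 2, axis=2
                    )
                    if d2.min() <= cut2:
                        hits[i, j] += 1
                        hits[j, i] += 1
    contacts = hits / n_frames >= params.occupancy_min
    for i in range(n):
        lo = max(0, i - params.exclude_neighbors)
        hi = min(n, i + params.exclude_neighbors + 1)
        contacts[i, lo:hi] = False
    return contacts


def build_network(
    correlation: np.ndarray,
    contacts: np.ndarray,
    nodes: Sequence[ResidueKey],
    params: NetworkParams | None = None,
) -> DynamicNetwork:
    """Weighted undirected residue graph on the contact edges.

    w_ij = −log|C_ij| with |C| floored at 1e-12; NaN-correlation edges
    are dropped.
    """
    params = params or NetworkParams()
    correlation = np.asarray(correlation)
    contacts = np.asarray(contacts, dtype=bool)
    if correlation.shape != contacts.shape:
        raise ValueError("correlation and contact shapes differ")
    nodes = list(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if not contacts[i, j]:
                continue
            c = correlation[i, j]
            if not np.isfinite(c):
                continue
            w = -math.log(max(abs(float(c)), 1e-12))
            g.add_edge(nodes[i], nodes[j], weight=w, correlation=float(c))
    return DynamicNetwork(
        nodes=nodes, correlation=correlation, contacts=contacts, graph=g,
        params=params,
    )


# ---------------------------------------------------------------------------
# Communities and betweenness
# ---------------------------------------------------------------------------


def _max_weighted_betweenness_edge(g: nx.Graph):
    bw = nx.edge_betweenness_centrality(g, weight="weight", normalized=False)
    # deterministic tie-break: highest betweenness, then lexicographic edge
    return max(bw, key=lambda e: (bw[e], tuple(sorted(e, reverse=True))))


def girvan_newman(
    network: DynamicNetwork, max_splits: int | None = None
) -> CommunityPartition:
    """Girvan–Newman communities of correlated residues.

    Edges with maximum weighted betweenness are removed iteratively; the
    partition with maximum (unweighted) modularity is returned.  The
    −log|C| weights steer edge removal but are distances, not
    affinities, so modularity is evaluated on the unweighted graph.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    base = [set(c) for c in nx.connected_components(g)]
    best = base
    best_q = nx.community.modularity(g, base) if g.number_of_edges() else 0.0
    gen = nx.community.girvan_newman(
        g, most_valuable_edge=_max_weighted_betweenness_edge
    )
    limit = max_splits if max_splits is not None else g.number_of_nodes() - 1
    for step, comm in enumerate(gen):
        comm = [set(c) for c in comm]
        q = nx.community.modularity(g, comm)
        if q > best_q + 1e-12:
            best_q, best = q, comm
        if step + 1 >= limit:
            break
    best = sorted(best, key=lambda c: (-len(c), sorted(c)))
    membership = {node: i for i, c in enumerate(best) for node in c}
    return CommunityPartition(
        communities=best, membership=membership, modularity=float(best_q)
    )


def edge_betweenness(network: DynamicNetwork) -> dict[tuple, float]:
    """Weighted-shortest-path edge betweenness over all ordered node
    pairs, unnormalized (twice the unordered count), with equal split
    over tied shortest paths."""
    bw = nx.edge_betweenness_centrality(
        network.graph, weight="weight", normalized=False
    )
    return {tuple(sorted(e)): 2.0 * v for e, v in bw.items()}


def critical_elements(
    network: DynamicNetwork,
    partition: CommunityPartition,
    betweenness: dict[tuple, float] | None = None,
) -> CommunityPartition:
    """Rank inter-community edges by betweenness; their endpoints are the
    critical nodes.  Returns the partition annotated in place."""
    if betweenness is None:
        betweenness = edge_betweenness(network)
    inter = [
        e
        for e in betweenness
        if partition.membership[e[0]] != partition.membership[e[1]]
    ]
    inter.sort(key=lambda e: (-betweenness[e], e))
    nodes: list[ResidueKey] = []
    for u, v in inter:
        for n in (u, v):
            if n not in nodes:
                nodes.append(n)
    partition.critical_edges = inter
    partition.critical_nodes = nodes
    return partition


# ---------------------------------------------------------------------------
# Paths
# ---------------------------------------------------------------------------


def suboptimal_paths(
    network: DynamicNetwork,
    source: ResidueKey,
    target: ResidueKey,
    tolerance_fraction: float = 0.0,
    max_paths: int = 100,
) -> list[PathResult]:
    """Weighted shortest path plus all simple paths within a fractional
    tolerance of the optimum (capped).

    A disconnected pair returns a single non-existent ``PathResult``
    ("no pathway exists") rather than raising.
    """
    g = network.graph
    for node in (source, target):
        if node not in g:
            raise KeyError(f"node {node} not in network")
    try:
        opt = nx.dijkstra_path_length(g, source, target, weight="weight")
    except nx.NetworkXNoPath:
        return [
            PathResult(
                source=source, target=target, nodes=[],
                total_weight=math.inf, exists=False,
            )
        ]
    limit = (1.0 + tolerance_fraction) * opt
    out: list[PathResult] = []
    for path in nx.shortest_simple_paths(g, source, target, weight="weight"):
        w = nx.path_weight(g, path, weight="weight")
        if w > limit + 1e-12:
            break
        out.append(
            PathResult(source=source, target=target, nodes=list(path),
                       total_weight=float(w))
        )
        if len(out) >= max_paths:
            break
    return out


def network_difference(
    net_a: DynamicNetwork, net_b: DynamicNetwork
) -> dict[str, dict[tuple, float]]:
    """Edges unique to each system and the shared set, with weights."""
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValueError("networks must share a node universe")

    def edges(net: DynamicNetwork) -> dict[tuple, float]:
        return {
            tuple(sorted(e)): d["weight"]
            for *e, d in net.graph.edges(data=True)
        }

    ea, eb = edges(net_a), edges(net_b)
    return {
        "unique_to_a": {e: ea[e] for e in ea.keys() - eb.keys()},
        "unique_to_b": {e: eb[e] for e in eb.keys() - ea.keys()},
        "shared": {e: ea[e] for e in ea.keys() & eb.keys()},
    }


# ---------------------------------------------------------------------------
# Brute-force references (used as oracles in the test suite)
# ---------------------------------------------------------------------------


def brute_force_shortest_path(
    g: nx.Graph, source, target
) -> tuple[list, float] | None:
    """Exhaustive simple-path enumeration; None when disconnected."""
    best: tuple[list, float] | None = None
    for path in nx.all_simple_paths(g, source, target):
        w = nx.path_weight(g, path, weight="weight")
        if best is None or w < best[1] - 1e-15:
            best = (list(path), w)
    return best


def brute_force_edge_betweenness(g: nx.Graph) -> dict[tuple, float]:
    """Ordered-pair shortest-path edge counts with equal split over ties,
    by explicit enumeration (small graphs only)."""
    out = {tuple(sorted(e)): 0.0 for e in g.edges}
    for s, t in itertools.permutations(g.nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        opt = nx.dijkstra_path_length(g, s, t, weight="weight")
        shortest = [
            p
            for p in nx.all_simple_paths(g, s, t)
            if abs(nx.path_weight(g, p, weight="weight") - opt) < 1e-12
        ]
        for p in shortest:
            for u, v in zip(p, p[1:]):
                out[tuple(sorted((u, v)))] += 1.0 / len(shortest)
    return out
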