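"""Topological characterization of a co-expression network.

Computes the thirteen-parameter topology profile used to compare immune gene
networks between tissue conditions: node and edge counts, mean degree,
diameter, radius, characteristic path length, average clustering coefficient,
density, degree heterogeneity, degree centralization, connected-component
count, degree assortativity, and modularity of a detected community
partition. Conventions follow the Cytoscape NetworkAnalyzer style where the
two differ from textbook definitions: clustering of degree < 2 nodes counts
as zero in the average, and shortest-path statistics are taken over finite
(within-component) pairs only, because thresholded co-expression networks are
routinely disconnected.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import CATEGORIES, GeneAnnotation

logger = logging.getLogger(__name__)

#: Canonical profile field order; fixed contract for vectors and JSON export.
PROFILE_FIELDS = (
    "nodes",
    "edges",
    "average_neighbors",
    "diameter",
    "radius",
    "path_length",
    "clustering_coefficient",
    "density",
    "heterogeneity",
    "centralization",
    "connected_components",
    "assortativity",
    "modularity",
)


@dataclass(frozen=True)
class TopologyProfile:
    """The ordered 13-parameter topological profile of one network."""

    nodes: int
    edges: int
    average_neighbors: float
    diameter: int
    radius: int
    path_length: float
    clustering_coefficient: float
    density: float
    heterogeneity: float
    centralization: float
    connected_components: int
    assortativity: float
    modularity: float

    def __post_init__(self) -> None:
        if self.nodes < 0 or self.edges < 0 or self.connected_components < 0:
            raise ValueError("counts must be non-negative")
        if self.radius > self.diameter:
            raise ValueError("radius cannot exceed diameter")

    def to_dict(self) -> dict[str, float]:
        """Field name -> value, in canonical order."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PROFILE_FIELDS],
                        dtype=float)


def _require_node(net: nx.Graph, node: Hashable) -> None:
    if node not in net:
        raise KeyError(f"unknown node: {node!r}")


def degree(net: nx.Graph, node: Hashable) -> int:
    """Number of links incident to ``node``."""
    _require_node(net, node)
    return net.degree(node)


def local_clustering(net: nx.Graph, node: Hashable) -> float:
    """Fraction of a node's neighbor pairs that are themselves linked.

    2*L_i / (k_i*(k_i - 1)) where L_i counts edges among the neighbors;
    defined as 0 for degree < 2 (no neighbor pairs exist).
    """
    _require_node(net, node)
    return nx.clustering(net, node)


def average_clustering(net: nx.Graph) -> float:
    """Mean of the local clustering coefficient over all nodes."""
    if net.number_of_nodes() == 0:
        logger.warning("average clustering of an empty network reported as 0")
        return 0.0
    return nx.average_clustering(net, count_zeros=True)


def density(net: nx.Graph) -> float:
    """Edges divided by the N*(N-1)/2 possible edges."""
    if net.number_of_nodes() < 2:
        logger.warning("density undefined for < 2 nodes; reported as 0")
        return 0.0
    return nx.density(net)


def heterogeneity(net: nx.Graph, convention: str = "vmr") -> float:
    """Dispersion of the degree distribution relative to its mean.

    ``convention="vmr"`` is the variance-to-mean ratio
    variance(k)/mean(k) (population variance;
    degrees are a complete enumeration, not a sample). The Cytoscape
    NetworkAnalyzer reports sqrt(variance)/mean, available as
    ``convention="cytoscape"``.
    """
    if convention not in ("vmr", "cytoscape"):
        raise ValueError("convention must be 'vmr' or 'cytoscape'")
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    if degrees.size == 0 or degrees.mean() == 0:
        raise ValueError("heterogeneity undefined: no edges in network")
    var = degrees.var()  # population variance
    if convention == "vmr":
        return float(var / degrees.mean())
    return float(np.sqrt(var) / degrees.mean())


def centralization(net: nx.Graph) -> float:
    """Freeman degree centralization: concentration of links on the hub.

    (N/(N-2)) * (k_max - <k>) / (N-1); equals 1 for a star and 0 for any
    regular graph.
    """
    n = net.number_of_nodes()
    if n < 3:
        logger.warning("centralization undefined for < 3 nodes; reported as 0")
        return 0.0
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    return float((n / (n - 2)) * (degrees.max() - degrees.mean()) / (n - 1))


def shortest_path_stats(net: nx.Graph) -> tuple[int, int, float]:
    """(diameter, radius, characteristic path length) over finite pairs.

    Distances are hop counts from breadth-first search. Pairs in different
    components have infinite distance and are excluded: the diameter is the
    maximum finite distance, the radius the minimum over nodes of each
    node's eccentricity within its own component, and the path length the
    mean of all finite pairwise distances.
    """
    if net.number_of_edges() == 0:
        raise ValueError("shortest-path statistics undefined without edges")
    eccentricities: list[int] = []
    total = 0
    pairs = 0
    for node in net.nodes:
        lengths = nx.single_source_shortest_path_length(net, node)
        finite = [d for d in lengths.values() if d > 0]
        if finite:
            eccentricities.append(max(finite))
            total += sum(finite)
            pairs += len(finite)
        else:
            eccentricities.append(0)  # singleton component
    # every unordered pair was visited from both endpoints
    return max(eccentricities), min(eccentricities), total / pairs


def connected_components(net: nx.Graph) -> int:
    """Number of maximal connected subgraphs."""
    return nx.number_connected_components(net)


def average_neighbors(net: nx.Graph) -> float:
    """Mean number of distinct neighbors per node (mean degree, 2L/N)."""
    n = net.number_of_nodes()
    if n == 0:
        logger.warning("average neighbors of an empty network reported as 0")
        return 0.0
    return 2.0 * net.number_of_edges() / n


def modularity(net: nx.Graph,
               partition: Sequence[Iterable[Hashable]]) -> float:
    """Newman modularity Q of a node partition.

    Q = (1/2L) * sum_ij (A_ij - k_i*k_j/2L) * delta(c_i, c_j): the excess of
    within-community edges over the expectation of a degree-preserving
    random graph. The partition must cover every node exactly once.
    """
    communities = [set(c) for c in partition]
    covered: set = set()
    for community in communities:
        overlap = covered & community
        if overlap:
            raise ValueError(f"partition not disjoint: {sorted(overlap)[:5]}")
        covered |= community
    missing = set(net.nodes) - covered
    if missing:
        raise ValueError(f"partition misses node(s): {sorted(missing)[:5]}")
    extra = covered - set(net.nodes)
    if extra:
        raise ValueError(f"partition contains unknown node(s): {sorted(extra)[:5]}")
    return nx.community.modularity(net, communities)


def detect_communities(net: nx.Graph, seed: int = 0) -> list[frozenset]:
    """Greedy modularity-maximizing community partition.

    Agglomerative (Clauset–Newman–Moore) merging from singletons; the
    procedure is deterministic for a fixed node insertion order, and the
    ``seed`` is part of the call contract so callers can thread one source
    of randomness through the pipeline. Communities are returned sorted by
    their smallest member for a stable output order.
    """
    if net.number_of_edges() == 0:
        raise ValueError("community detection requires at least one edge")
    del seed  # deterministic algorithm; kept for interface stability
    communities = nx.community.greedy_modularity_communities(net)
    return sorted((frozenset(c) for c in communities),
                  key=lambda c: min(map(str, c)))


def assortativity(net: nx.Graph) -> float:
    """Pearson correlation of degrees across edge endpoints.

    Each undirected edge contributes both orientations. Undefined (NaN, with
    a warning) when endpoint degrees have zero variance, e.g. stars, cycles
    and other regular graphs.
    """
    if net.number_of_edges() == 0:
        raise ValueError("assortativity undefined without edges")
    deg = dict(net.degree())
    x, y = [], []
    for u, v in net.edges():
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x, y = np.array(x, dtype=float), np.array(y, dtype=float)
    if x.var() == 0 or y.var() == 0:
        logger.warning("assortativity undefined (zero endpoint-degree "
                       "variance); reported as NaN")
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def hub(net: nx.Graph) -> tuple[Hashable, int]:
    """The maximum-degree node; ties broken lexicographically by gene ID."""
    if net.number_of_nodes() == 0:
        raise ValueError("hub undefined for an empty network")
    best = min(net.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    ties = [n for n, d in net.degree() if d == best[1]]
    if len(ties) > 1:
        logger.info("hub degree %d shared by %d nodes; lexicographic "
                    "tie-break selected %r", best[1], len(ties), best[0])
    return best


def composition(net: nx.Graph, ann: GeneAnnotation) -> dict[str, float]:
    """Fraction of network nodes per immune functional category."""
    if net.number_of_nodes() == 0:
        raise ValueError("composition undefined for an empty network")
    counts = dict.fromkeys(CATEGORIES, 0)
    for node in net.nodes:
        category = ann.get(node)
        if category is None:
            raise KeyError(f"node {node!r} has no category annotation")
        counts[category] += 1
    n = net.number_of_nodes()
    return {cat: counts[cat] / n for cat in CATEGORIES}


def topology_profile(net: nx.Graph, seed: int = 0) -> TopologyProfile:
    """Assemble the full 13-parameter profile of one network."""
    if net.number_of_edges() == 0:
        raise ValueError("topology profile requires at least one edge")
    diameter, radius, path_length = shortest_path_stats(net)
    partition = detect_communities(net, seed=seed)
    return TopologyProfile(
        nodes=net.number_of_nodes(),
        edges=net.number_of_edges(),
        average_neighbors=average_neighbors(net),
        diameter=diameter,
        radius=radius,
        path_length=path_length,
        clustering_coefficient=average_clustering(net),
        density=density(net),
        heterogeneity=heterogeneity(net),
        centralization=centralization(net),
        connected_components=connected_components(net),
        assortativity=assortativity(net),
        modularity=modularity(net, partition),
    )


def node_report(net: nx.Graph,
                ann: GeneAnnotation | None = None) -> pd.DataFrame:
    """Per-node table: gene_id, degree, clustering, category."""
    clustering = nx.clustering(net)
    rows = [{
        "gene_id": node,
        "degree": net.degree(node),
        "clustering": clustering[node],
        "category": ann.get(node, "") if ann is not None else "",
    } for node in sorted(net.nodes, key=str)]
    return pd.DataFrame(rows, columns=["gene_id", "degree", "clustering",
                                       "category"])


def write_profile_json(profile: TopologyProfile, path: str | Path) -> None:
    """Write the profile as JSON with the 13 keys in canonical order."""
    with open(path, "w") as handle:
        json.dump(profile.to_dict(), handle, indent=2, allow_nan=True)
        handle.write("\n")


def read_profile_json(path: str | Path) -> TopologyProfile:
    with open(path) as handle:
        payload = json.load(handle)
    missing = set(PROFILE_FIELDS) - set(payload)
    if missing:
        raise ValueError(f"profile JSON missing fields: {sorted(missing)}")
    return TopologyProfile(**{k: payload[k] for k in PROFILE_FIELDS})
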