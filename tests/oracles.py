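"""Brute-force graph-metric oracles for cross-checking the implementation.

Everything here works on a plain node list + edge set with no graph library:
hand-rolled BFS, union-find, triangle counting and direct formula
evaluation. Deliberately slow and simple; only used on tiny graphs.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def degrees(nodes, edges):
    adj = adjacency(nodes, edges)
    return {n: len(adj[n]) for n in nodes}


def local_clustering(nodes, edges, node):
    adj = adjacency(nodes, edges)
    nbrs = adj[node]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for a, b in combinations(sorted(nbrs, key=str), 2)
                if b in adj[a])
    return 2.0 * links / (k * (k - 1))


def average_clustering(nodes, edges):
    return sum(local_clustering(nodes, edges, n) for n in nodes) / len(nodes)


def density(nodes, edges):
    n = len(nodes)
    return len(edges) / (n * (n - 1) / 2)


def average_neighbors(nodes, edges):
    deg = degrees(nodes, edges)
    return sum(deg.values()) / len(nodes)


def heterogeneity(nodes, edges, convention="vmr"):
    deg = list(degrees(nodes, edges).values())
    mean = sum(deg) / len(deg)
    var = sum((d - mean) ** 2 for d in deg) / len(deg)
    if convention == "vmr":
        return var / mean
    return math.sqrt(var) / mean


def centralization(nodes, edges):
    deg = list(degrees(nodes, edges).values())
    n = len(deg)
    mean = sum(deg) / n
    return (n / (n - 2)) * (max(deg) - mean) / (n - 1)


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def shortest_path_stats(nodes, edges):
    adj = adjacency(nodes, edges)
    eccentricities = []
    total = 0
    pairs = 0
    for node in nodes:
        finite = [d for d in bfs_distances(adj, node).values() if d > 0]
        eccentricities.append(max(finite) if finite else 0)
        total += sum(finite)
        pairs += len(finite)
    return max(eccentricities), min(eccentricities), total / pairs


def connected_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(n) for n in nodes})


def _pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    if vx == 0 or vy == 0:
        return math.nan
    return cov / math.sqrt(vx * vy)


def assortativity(nodes, edges):
    deg = degrees(nodes, edges)
    x, y = [], []
    for u, v in edges:
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    return _pearson(x, y)


def modularity(nodes, edges, partition):
    """Direct double-sum evaluation of Q over the adjacency matrix."""
    community_of = {}
    for idx, community in enumerate(partition):
        for node in community:
            community_of[node] = idx
    edge_set = {frozenset(e) for e in edges}
    deg = degrees(nodes, edges)
    two_l = 2 * len(edges)
    q = 0.0
    for i in nodes:
        for j in nodes:
            if community_of[i] != community_of[j]:
                continue
            a_ij = 1.0 if i != j and frozenset((i, j)) in edge_set else 0.0
            q += a_ij - deg[i] * deg[j] / two_l
    return q / two_l
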