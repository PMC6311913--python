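"""Brute-force, first-principles graph descriptors for small graphs.

Everything here works from the adjacency structure alone (BFS, explicit
path enumeration, explicit subset enumeration) so it is independent of the
igraph-backed implementation it cross-checks. Intended for |V| <= 12.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: list[set[int]], s: int) -> list[int]:
    d = [-1] * len(adj)
    d[s] = 0
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if d[v] < 0:
                d[v] = d[u] + 1
                q.append(v)
    return d


def adjacency(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def all_shortest_paths(adj, s, t):
    """Every shortest s-t path, by DFS over the BFS predecessor DAG."""
    d = bfs_distances(adj, s)
    preds: dict[int, list[int]] = {s: []}
    for v in range(len(adj)):
        preds.setdefault(v, [])
        for u in adj[v]:
            if d[u] == d[v] - 1:
                preds[v].append(u)
    out = []

    def walk(v, tail):
        if v == s:
            out.append([s] + tail)
            return
        for u in preds[v]:
            walk(u, [v] + tail)

    walk(t, [])
    return out


def node_betweenness(n, edges):
    adj = adjacency(n, edges)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def edge_betweenness(n, edges):
    adj = adjacency(n, edges)
    eb = {tuple(sorted(e)): 0.0 for e in edges}
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t)
        for p in paths:
            for a, b in zip(p, p[1:]):
                eb[tuple(sorted((a, b)))] += 1.0 / len(paths)
    return np.array([eb[tuple(sorted(e))] for e in edges])


def closeness(n, edges):
    adj = adjacency(n, edges)
    return np.array(
        [(n - 1) / sum(bfs_distances(adj, s)) for s in range(n)]
    )


def coreness(n, edges):
    adj = adjacency(n, edges)
    deg = {v: len(adj[v]) for v in range(n)}
    core: dict[int, int] = {}
    alive = set(range(n))
    k = 0
    while alive:
        while True:
            peel = [v for v in alive if deg[v] <= k]
            if not peel:
                break
            for v in peel:
                core[v] = k
                alive.discard(v)
                for u in adj[v]:
                    if u in alive:
                        deg[u] -= 1
        if alive:
            k += 1
    return np.array([core[v] for v in range(n)])


def burt_constraint(n, edges):
    adj = adjacency(n, edges)
    out = np.zeros(n)
    for i in range(n):
        nbrs = adj[i]
        if not nbrs:
            out[i] = 0.0
            continue
        p = {j: 1.0 / len(nbrs) for j in nbrs}
        c = 0.0
        for j in nbrs:
            indirect = sum(
                p[q] * (1.0 / len(adj[q])) for q in nbrs if q != j and j in adj[q]
            )
            c += (p[j] + indirect) ** 2
        out[i] = c
    return out


def hub_score(n, edges):
    """Dominant adjacency eigenvector, scaled to max 1 (symmetric graph)."""
    A = np.zeros((n, n))
    for a, b in edges:
        A[a, b] = A[b, a] = 1.0
    w, V = np.linalg.eigh(A)
    v = np.abs(V[:, np.argmax(w)])
    return v / v.max()


def cocitation_mean(n, edges):
    A = np.zeros((n, n))
    for a, b in edges:
        A[a, b] = A[b, a] = 1.0
    C = A @ A
    np.fill_diagonal(C, 0.0)
    return C.sum() / (n * (n - 1)) if n > 1 else 0.0


def local_transitivity(n, edges):
    adj = adjacency(n, edges)
    out = np.zeros(n)
    for v in range(n):
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
        out[v] = links / (k * (k - 1) / 2)
    return out


def global_transitivity(n, edges):
    adj = adjacency(n, edges)
    triangles = 0
    triples = 0
    for v in range(n):
        k = len(adj[v])
        triples += k * (k - 1) // 2
        triangles += sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
    return triangles / triples if triples else 0.0


def diameter_and_ecc(n, edges):
    adj = adjacency(n, edges)
    ecc = np.array([max(bfs_distances(adj, s)) for s in range(n)], dtype=float)
    return ecc.max(), ecc


def girth(n, edges):
    """Shortest cycle length: for each edge, shortest alternative path + 1."""
    best = np.inf
    for a, b in edges:
        rest = [e for e in edges if tuple(sorted(e)) != tuple(sorted((a, b)))]
        adj = adjacency(n, rest)
        d = bfs_distances(adj, a)[b]
        if d > 0:
            best = min(best, d + 1)
    return 0.0 if np.isinf(best) else float(best)


def average_path_length(n, edges):
    adj = adjacency(n, edges)
    total = sum(
        bfs_distances(adj, s)[t] for s, t in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def articulation_count(n, edges):
    def connected(vertices, es):
        vs = list(vertices)
        if not vs:
            return True
        adj = adjacency(n, es)
        seen = {vs[0]}
        q = deque([vs[0]])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v in vertices and v not in seen:
                    seen.add(v)
                    q.append(v)
        return seen == set(vertices)

    count = 0
    for v in range(n):
        rest_edges = [e for e in edges if v not in e]
        if not connected(set(range(n)) - {v}, rest_edges):
            count += 1
    return count


def connected_subgraph_count(n, edges, size):
    adj = adjacency(n, edges)
    count = 0
    for subset in itertools.combinations(range(n), size):
        sub = set(subset)
        sub_edges = [
            (a, b) for a, b in itertools.combinations(subset, 2) if b in adj[a]
        ]
        seen = {subset[0]}
        q = deque([subset[0]])
        sub_adj = adjacency(n, sub_edges)
        while q:
            u = q.popleft()
            for v in sub_adj[u]:
                if v in sub and v not in seen:
                    seen.add(v)
                    q.append(v)
        if seen == sub:
            count += 1
    return count


def density(n, edges):
    return len(edges) / (n * (n - 1) / 2)


def modularity_of(n, edges, membership):
    """Newman modularity of a given partition."""
    m = len(edges)
    deg = np.zeros(n)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    q = 0.0
    for c in set(membership):
        nodes = {v for v in range(n) if membership[v] == c}
        lc = sum(1 for a, b in edges if a in nodes and b in nodes)
        dc = sum(deg[v] for v in nodes)
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def reference_block(n, edges):
    """The 23 directly-brute-forceable descriptors in implementation order.

    Modularity (index 15 of the implementation block) depends on the chosen
    community algorithm and is checked separately; this returns a dict keyed
    by feature name for the rest.
    """
    deg = np.array([sum(1 for e in edges if v in e) for v in range(n)], float)
    bet = node_betweenness(n, edges)
    core = coreness(n, edges)
    diam, ecc = diameter_and_ecc(n, edges)
    return {
        "net.A-degree": deg.mean(),
        "net.V-degree": deg.var(),
        "net.A-closeness": closeness(n, edges).mean(),
        "net.A-Nbetweenness": bet.mean(),
        "net.Var-Vbetweenness": bet.var(),
        "net.A-Ebetweenness": edge_betweenness(n, edges).mean(),
        "net.A-coreness": core.mean(),
        "net.V-coreness": core.var(),
        "net.A-Burts": burt_constraint(n, edges).mean(),
        "net.A-hubscore": hub_score(n, edges).mean(),
        "net.A-cocitation": cocitation_mean(n, edges),
        "net.A-bibliographic": cocitation_mean(n, edges),
        "net.A-localtrans": local_transitivity(n, edges).mean(),
        "net.transitivity": global_transitivity(n, edges),
        "net.Densith": density(n, edges),
        "net.diameter": diam,
        "net.girth": girth(n, edges),
        "net.avgpathlen": average_path_length(n, edges),
        "net.N-articulation": float(articulation_count(n, edges)),
        "net.N-motif3": float(connected_subgraph_count(n, edges, 3)),
        "net.N-motif4": float(connected_subgraph_count(n, edges, 4)),
        "net.A-eccentricity": ecc.mean(),
        "net.max-coreness": float(core.max()),
    }
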