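"""Independent brute-force graph oracles used to cross-check the
networkx-backed implementations.  Everything here is written from the
definitions (adjacency matrices, explicit BFS, path enumeration) and never
calls the library routines it checks."""

from __future__ import annotations

from collections import deque
from itertools import combinations


def undirected_adj(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def bfs_dists(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def degrees(nodes, edges):
    adj = undirected_adj(nodes, edges)
    return {n: len(adj[n]) for n in nodes}


def closeness_wf(nodes, edges):
    """Wasserman-Faust closeness: ((r-1)/(n-1)) * ((r-1)/sum_d)."""
    adj = undirected_adj(nodes, edges)
    n = len(adj)
    out = {}
    for v in adj:
        dist = bfs_dists(adj, v)
        r = len(dist)
        total = sum(dist.values())
        out[v] = 0.0 if total == 0 or n <= 1 else ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def clustering(nodes, edges):
    adj = undirected_adj(nodes, edges)
    out = {}
    for v in adj:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a])
        out[v] = 2 * links / (k * (k - 1))
    return out


def characteristic_path_length(nodes, edges):
    adj = undirected_adj(nodes, edges)
    total = pairs = 0
    for v in adj:
        for u, d in bfs_dists(adj, v).items():
            if u != v:
                total += d
                pairs += 1
    return total / pairs if pairs else 0.0


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate every shortest s-t path (as node tuples)."""
    if t not in dist:
        return []
    paths = []

    def walk(node, acc):
        if node == s:
            paths.append(tuple(reversed(acc + [s])))
            return
        for p in adj[node]:
            if dist.get(p, -1) == dist[node] - 1:
                walk(p, acc + [node])

    walk(t, [])
    return paths


def betweenness(nodes, edges):
    """Normalised betweenness, endpoints excluded, via explicit shortest-path
    enumeration (feasible for n <= ~20)."""
    adj = undirected_adj(nodes, edges)
    n = len(adj)
    score = {v: 0.0 for v in adj}
    node_list = sorted(adj)
    for i, s in enumerate(node_list):
        dist = bfs_dists(adj, s)
        for t in node_list[i + 1 :]:
            paths = _all_shortest_paths(adj, s, t, dist)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1 / len(paths)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        score = {v: x / norm for v, x in score.items()}
    return score


def scc_by_reachability(nodes, directed_edges):
    """Strongly connected components as mutual-reachability classes,
    computed from the transitive closure (O(n^3))."""
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for i in range(n):
        reach[i][i] = True
    for u, v in directed_edges:
        reach[idx[u]][idx[v]] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                row_i, row_k = reach[i], reach[k]
                for j in range(n):
                    if row_k[j]:
                        row_i[j] = True
    seen = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp = {nodes[j] for j in range(n) if reach[i][j] and reach[j][i]}
        seen |= {idx[c] for c in comp}
        comps.append(frozenset(comp))
    return comps
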