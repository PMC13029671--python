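"""Independent brute-force graph oracles used to validate the topology
statistics.  Everything here works from a plain edge list by exhaustive
path enumeration / triple counting, deliberately avoiding networkx."""

from __future__ import annotations

from itertools import combinations


def _adjacency(nodes, edges):
    adj = {v: {} for v in nodes}
    for u, v, w in edges:
        adj[u][v] = w
        adj[v][u] = w
    return adj


def _all_simple_paths(adj, s, t):
    """Yield (length_in_weights, length_in_hops) of every simple s-t path."""
    stack = [(s, {s}, 0.0, 0)]
    while stack:
        node, seen, w, hops = stack.pop()
        for nxt, wt in adj[node].items():
            if nxt == t:
                yield w + wt, hops + 1
            elif nxt not in seen:
                stack.append((nxt, seen | {nxt}, w + wt, hops + 1))


def shortest_distances(nodes, edges, weighted=True):
    """{(u, v): distance} over connected unordered pairs, by enumerating
    every simple path and taking the minimum."""
    adj = _adjacency(nodes, edges)
    out = {}
    for u, v in combinations(nodes, 2):
        best = None
        for w, hops in _all_simple_paths(adj, u, v):
            d = w if weighted else hops
            if best is None or d < best:
                best = d
        if best is not None:
            out[(u, v)] = best
    return out


def betweenness_normalized(nodes, edges):
    """Normalized shortest-path betweenness by explicit enumeration of all
    minimal-hop simple paths per pair (unweighted)."""
    adj = _adjacency(nodes, edges)
    n = len(nodes)
    b = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            for nxt in adj[node]:
                if nxt == t:
                    paths.append(path + [t])
                elif nxt not in path:
                    stack.append((nxt, path + [nxt]))
        if not paths:
            continue
        minlen = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == minlen]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            b[v] += through / len(shortest)
    denom = (n - 1) * (n - 2) / 2
    return {v: (val / denom if denom else 0.0) for v, val in b.items()}


def centralization(betweenness: dict) -> float:
    n = len(betweenness)
    if n < 3:
        return 0.0
    bmax = max(betweenness.values())
    return sum(bmax - v for v in betweenness.values()) / (n - 1)


def transitivity(nodes, edges) -> float:
    """3 x triangles / connected triples, by direct counting."""
    eset = {frozenset((u, v)) for u, v, _ in edges}
    neigh = {v: set() for v in nodes}
    for u, v, _ in edges:
        neigh[u].add(v)
        neigh[v].add(u)
    triangles = sum(1 for a, b, c in combinations(nodes, 3)
                    if frozenset((a, b)) in eset and frozenset((b, c)) in eset
                    and frozenset((a, c)) in eset)
    triples = sum(len(neigh[v]) * (len(neigh[v]) - 1) // 2 for v in nodes)
    return 3.0 * triangles / triples if triples else 0.0


def density(nodes, edges) -> float:
    n = len(nodes)
    return 2.0 * len(edges) / (n * (n - 1)) if n > 1 else 0.0


def modularity_q(nodes, edges, partition) -> float:
    """Q = sum_c (L_c / m - (d_c / 2m)^2) for an unweighted graph."""
    m = len(edges)
    if m == 0:
        return 0.0
    deg = {v: 0 for v in nodes}
    for u, v, _ in edges:
        deg[u] += 1
        deg[v] += 1
    q = 0.0
    for comm in partition:
        lc = sum(1 for u, v, _ in edges if u in comm and v in comm)
        dc = sum(deg[v] for v in comm)
        q += lc / m - (dc / (2.0 * m)) ** 2
    return q


def random_test_graph(rng, max_nodes=15, max_edge_factor=1.6):
    """Sparse random weighted graph as (nodes, edges) with edges
    (u, v, distance); sparse so path enumeration stays tractable."""
    n = int(rng.integers(4, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    possible = list(combinations(nodes, 2))
    m = int(rng.integers(n - 1, min(len(possible), int(max_edge_factor * n)) + 1))
    idx = rng.choice(len(possible), size=m, replace=False)
    edges = [(possible[i][0], possible[i][1],
              float(rng.uniform(0.02, 1.0))) for i in idx]
    return nodes, edges
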