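"""Independent brute-force oracles for graph metrics, kept deliberately
separate from the package implementation.

All edge lengths used with these oracles should be dyadic rationals
(multiples of 1/8) so shortest-path ties are exact in both rational and
floating arithmetic.
"""

from fractions import Fraction
from itertools import combinations


def _simple_paths(adj, s, t):
    """All simple paths s -> t in an adjacency dict {u: {v: length}}."""
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))


def brute_degree(nodes, weights):
    """Weighted degree (strength) per node; weights: {(u,v): w} undirected."""
    deg = {n: Fraction(0) for n in nodes}
    for (u, v), w in weights.items():
        deg[u] += w
        deg[v] += w
    return deg


def brute_clustering(nodes, weights):
    """Unweighted local clustering coefficient per node."""
    neigh = {n: set() for n in nodes}
    for u, v in weights:
        neigh[u].add(v)
        neigh[v].add(u)
    cc = {}
    for n in nodes:
        k = len(neigh[n])
        if k < 2:
            cc[n] = Fraction(0)
            continue
        links = sum(
            1 for a, b in combinations(sorted(neigh[n]), 2) if b in neigh[a]
        )
        cc[n] = Fraction(links, k * (k - 1) // 2)
    return cc


def brute_betweenness(nodes, lengths, normalized=True):
    """Shortest-path betweenness by exhaustive simple-path enumeration.

    lengths: {(u, v): Fraction} undirected edge lengths. Returns exact
    Fractions; normalization divides by (n-1)(n-2)/2.
    """
    adj = {n: {} for n in nodes}
    for (u, v), d in lengths.items():
        adj[u][v] = d
        adj[v][u] = d
    bet = {n: Fraction(0) for n in nodes}
    for s, t in combinations(sorted(nodes), 2):
        paths = list(_simple_paths(adj, s, t))
        if not paths:
            continue
        plens = [sum(adj[a][b] for a, b in zip(p, p[1:])) for p in paths]
        best = min(plens)
        shortest = [p for p, d in zip(paths, plens) if d == best]
        for p in shortest:
            for interior in p[1:-1]:
                bet[interior] += Fraction(1, len(shortest))
    n = len(nodes)
    if normalized and n > 2:
        scale = Fraction(2, (n - 1) * (n - 2))
        bet = {k: v * scale for k, v in bet.items()}
    return bet


def brute_geodesics(nodes, lengths):
    """All-pairs shortest path lengths by simple-path enumeration; None
    where disconnected."""
    adj = {n: {} for n in nodes}
    for (u, v), d in lengths.items():
        adj[u][v] = d
        adj[v][u] = d
    out = {}
    for s, t in combinations(sorted(nodes), 2):
        paths = list(_simple_paths(adj, s, t))
        if not paths:
            out[(s, t)] = None
            continue
        out[(s, t)] = min(
            sum(adj[a][b] for a, b in zip(p, p[1:])) for p in paths
        )
    return out


def dyadic_weights(edges):
    """Deterministic dyadic COR weights in (0, 1) for a list of edges."""
    return {
        tuple(sorted(e)): Fraction((i % 6) + 1, 8) for i, e in enumerate(sorted(map(tuple, map(sorted, edges))))
    }
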