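"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain BFS, exhaustive path
enumeration, exact combinatorics — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb


def bfs_distances(adj: dict, source) -> dict:
    """Plain breadth-first search distances from source."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s→t paths by exhaustive breadth-first enumeration."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(path)
            return
        for u in adj[v]:
            if dist.get(u) == dist[v] + 1 and dist.get(t, 1e9) >= dist[u]:
                extend(path + [u])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_betweenness(adj: dict) -> dict:
    """Pair-normalized betweenness by exhaustive shortest-path enumeration."""
    nodes = list(adj)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: out[v] / norm for v in nodes}


def brute_closeness(adj: dict) -> dict:
    """Closeness with the reachable-set correction, from raw BFS."""
    nodes = list(adj)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        r = len(dist) - 1
        s = sum(dist.values())
        out[v] = (r / (n - 1)) * (r / s) if r > 0 else 0.0
    return out


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for a hypergeometric draw, by summation."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def naive_mutual_information(x, y, bins: int) -> float:
    """Plug-in MI in nats from dict-based histograms (pure Python).

    Equal-frequency binning by stable rank: the i-th smallest value goes
    to bin floor(i * bins / n).
    """
    from math import log

    n = len(x)

    def assign(vals):
        order = sorted(range(n), key=lambda i: (vals[i], i))
        b = [0] * n
        for rank, i in enumerate(order):
            b[i] = (rank * bins) // n
        return b

    bx, by = assign(list(x)), assign(list(y))
    joint: dict = {}
    mx: dict = {}
    my: dict = {}
    for a, b in zip(bx, by):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        mx[a] = mx.get(a, 0) + 1
        my[b] = my.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * log(p / ((mx[a] / n) * (my[b] / n)))
    return mi
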