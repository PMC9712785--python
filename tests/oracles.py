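"""Independent brute-force oracles used by the property tests.

Each function recomputes a quantity from first principles (exhaustive
enumeration, direct definitions), deliberately avoiding the code paths and
libraries the implementation uses.
"""

from __future__ import annotations

import math
from collections import deque

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# -- graph centralities -----------------------------------------------------

def _bfs_dist_sigma(adj: dict, source):
    """Distances and shortest-path counts from one source (plain BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(graph) -> dict:
    """Normalized betweenness by direct sigma_st(v)/sigma_st summation."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = {u: list(graph.neighbors(u)) for u in nodes}
    dist = {}
    sigma = {}
    for u in nodes:
        dist[u], sigma[u] = _bfs_dist_sigma(adj, u)
    bc = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            total = sigma[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / total
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: b * scale for v, b in bc.items()}
    return bc


def brute_closeness(graph) -> dict:
    """Wasserman-Faust closeness: (r-1)/(n-1) * (r-1)/sum(dist to reachable)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = {u: list(graph.neighbors(u)) for u in nodes}
    out = {}
    for u in nodes:
        dist, _ = _bfs_dist_sigma(adj, u)
        r = len(dist)  # reachable including u
        total = sum(dist.values())
        if r <= 1 or total == 0:
            out[u] = 0.0
        else:
            out[u] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


# -- seed matching ----------------------------------------------------------

def brute_seed_sites(mirna: str, target: str) -> list[tuple[int, int, str]]:
    """Exhaustive antiparallel base-by-base seed scan (linear targets).

    Returns (start, end, site_type) per 6mer-core occurrence, classified by
    checking the m8 and A1 positions directly.
    """
    m = mirna.upper().replace("U", "T")
    t = target.upper().replace("U", "T")
    sites = []
    for i in range(len(t) - 5):
        # core: target[i .. i+5] pairs miRNA positions 7 .. 2 antiparallel
        if not all(_COMP[t[i + 5 - j]] == m[1 + j] for j in range(6)):
            continue
        m8 = i >= 1 and _COMP[t[i - 1]] == m[7]
        a1 = i + 6 < len(t) and t[i + 6] == "A"
        if m8 and a1:
            sites.append((i - 1, i + 7, "8mer"))
        elif m8:
            sites.append((i - 1, i + 6, "7mer_m8"))
        elif a1:
            sites.append((i, i + 7, "7mer_A1"))
        else:
            sites.append((i, i + 6, "6mer"))
    return sites


# -- hypergeometric upper tail ---------------------------------------------

def brute_hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(n, K) + 1)
        if n - x <= N - K
    ) / total


# -- Benjamini-Hochberg -----------------------------------------------------

def brute_bh(p_values) -> list[float]:
    """BH step-up by the direct definition: q_i = min_{j>=i} p_(j) * m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q
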