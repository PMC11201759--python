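"""Independent brute-force oracles used to validate the implementation.

Deliberately naive and self-contained: distances by Floyd–Warshall,
betweenness by explicit enumeration of every shortest path, Fisher
p-values by exact enumeration of all 2x2 tables with fixed margins
(rational arithmetic), and a literal step-up implementation of the
Benjamini–Hochberg adjustment.  Nothing here calls the code under test
or the libraries it delegates to.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


# ---------------------------------------------------------------------------
# graph metrics
# ---------------------------------------------------------------------------

def floyd_warshall(nodes: list, edges: set[tuple]) -> dict:
    inf = math.inf
    d = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    adj = {u: set() for u in nodes}
    for a, b in edges:
        d[a][b] = d[b][a] = 1
        adj[a].add(b)
        adj[b].add(a)
    for k in nodes:
        for i in nodes:
            if d[i][k] == inf:
                continue
            for j in nodes:
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def _all_shortest_paths(adj, dist, s, t):
    """Every shortest s-t path, by depth-first enumeration with pruning."""
    target = dist[s][t]
    paths = []

    def dfs(node, path):
        steps = len(path) - 1
        if node == t:
            if steps == target:
                paths.append(tuple(path))
            return
        for nb in adj[node]:
            if nb not in path and steps + 1 + dist[nb][t] <= target:
                dfs(nb, path + [nb])

    dfs(s, [s])
    return paths


def brute_force_metrics(edges: list[tuple]) -> dict[object, dict[str, float]]:
    """All six node metrics of an undirected simple graph, from scratch.

    Returns ``{node: {bc, cce, nc, cco, avp, v}}``.  Betweenness is the
    unnormalized count over unordered pairs of the fraction of shortest
    paths passing through the node; closeness is (V-1)/sum(d) within the
    node's component.
    """
    eset = {tuple(sorted(e)) for e in edges}
    nodes = sorted({n for e in eset for n in e})
    adj = {u: set() for u in nodes}
    for a, b in eset:
        adj[a].add(b)
        adj[b].add(a)
    dist = floyd_warshall(nodes, eset)

    # connected components
    comp_of = {}
    for u in nodes:
        comp_of[u] = frozenset(v for v in nodes if dist[u][v] < math.inf)

    bc = {u: 0.0 for u in nodes}
    for s, t in combinations(nodes, 2):
        if dist[s][t] == math.inf:
            continue
        paths = _all_shortest_paths(adj, dist, s, t)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                bc[v] += through / len(paths)

    out = {}
    for u in nodes:
        comp = comp_of[u]
        V = len(comp)
        dsum = sum(dist[u][v] for v in comp if v != u)
        k = len(adj[u])
        nbr_pairs = list(combinations(sorted(adj[u]), 2))
        closed = sum(1 for a, b in nbr_pairs if tuple(sorted((a, b))) in eset)
        out[u] = {
            "bc": bc[u],
            "cce": (V - 1) / dsum if dsum else 0.0,
            "nc": sum(len(adj[v]) for v in adj[u]) / k if k else 0.0,
            "cco": closed / len(nbr_pairs) if k >= 2 else 0.0,
            "avp": dsum / (V - 1) if V > 1 else 0.0,
            "v": V,
        }
    return out


# ---------------------------------------------------------------------------
# Fisher exact test (two-sided) by exhaustive table enumeration
# ---------------------------------------------------------------------------

def fisher_two_sided_enum(n_universe: int, n_deg: int, n_term: int, n_overlap: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities.

    Enumerates every 2x2 table with the observed margins and sums the
    (exact, rational) probabilities of tables no more likely than the
    observed one, with the conventional (1 + 1e-7) relative tie guard.
    """
    lo = max(0, n_deg + n_term - n_universe)
    hi = min(n_deg, n_term)
    denom = math.comb(n_universe, n_term)
    pmf = {
        k: Fraction(math.comb(n_deg, k) * math.comb(n_universe - n_deg, n_term - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = float(pmf[n_overlap])
    gate = p_obs * (1 + 1e-7)
    total = sum(p for p in pmf.values() if float(p) <= gate)
    return float(total)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg, literal step-up
# ---------------------------------------------------------------------------

def bh_step_up(p_values) -> list[float]:
    """Hand-computed BH: sort, scale by n/rank, enforce monotone from the top."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adj = [0.0] * n
    running = 1.0
    for pos in range(n - 1, -1, -1):
        i = order[pos]
        running = min(running, p_values[i] * n / (pos + 1))
        adj[i] = running
    return adj
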