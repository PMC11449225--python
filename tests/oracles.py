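"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, closed
formulas) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math


def max_clique_size(nodes, edges) -> int:
    """Largest clique by decreasing-size exhaustive subset search."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}
    for size in range(len(nodes), 0, -1):
        for combo in itertools.combinations(nodes, size):
            if all(
                frozenset((a, b)) in edge_set
                for a, b in itertools.combinations(combo, 2)
            ):
                return size
    return 0


def shortest_path_matrix(nodes, edges) -> dict:
    """All-pairs shortest path lengths by Floyd-Warshall."""
    nodes = list(nodes)
    inf = math.inf
    dist = {(a, b): (0 if a == b else inf) for a in nodes for b in nodes}
    for a, b in edges:
        dist[(a, b)] = dist[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def betweenness_closeness(nodes, edges):
    """Normalized betweenness and closeness by explicit path counting.

    Shortest-path counts via dynamic programming over distance layers;
    betweenness normalized by (n-1)(n-2)/2, closeness as (n-1)/sum(d).
    """
    nodes = list(nodes)
    n = len(nodes)
    dist = shortest_path_matrix(nodes, edges)
    adj = {a: set() for a in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    # sigma[s][t]: number of shortest s-t paths
    sigma = {}
    for s in nodes:
        counts = {s: 1}
        order = sorted(
            (t for t in nodes if dist[(s, t)] < math.inf),
            key=lambda t: dist[(s, t)],
        )
        for t in order:
            if t == s:
                continue
            counts[t] = sum(
                counts.get(p, 0)
                for p in adj[t]
                if dist[(s, p)] + 1 == dist[(s, t)]
            )
        sigma[s] = counts

    betweenness = {}
    for v in nodes:
        total = 0.0
        for s, t in itertools.combinations([x for x in nodes if x != v], 2):
            if sigma[s].get(t, 0) == 0:
                continue
            if dist[(s, v)] + dist[(v, t)] == dist[(s, t)]:
                total += sigma[s][v] * sigma[v][t] / sigma[s][t]
        betweenness[v] = total / ((n - 1) * (n - 2) / 2)
    closeness = {
        v: (n - 1) / sum(dist[(v, t)] for t in nodes if t != v)
        for v in nodes
    }
    return betweenness, closeness


def fitch_min_changes(tree_children, leaf_states) -> int:
    """Minimum number of state changes over all internal labelings.

    ``tree_children``: mapping internal node -> (child, child); leaves are
    the keys of ``leaf_states`` (states 0/1). Exhaustive enumeration over
    all 2^k internal labelings.
    """
    internals = sorted(tree_children)
    edges = [
        (parent, child)
        for parent in internals
        for child in tree_children[parent]
    ]
    best = len(edges) + 1
    for bits in itertools.product((0, 1), repeat=len(internals)):
        labels = dict(zip(internals, bits))
        labels.update(leaf_states)
        changes = sum(
            1 for p, c in edges if labels[p] != labels[c]
        )
        best = min(best, changes)
    return best


def welch_t(a, b):
    """Closed-form Welch t statistic and Satterthwaite df."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def ols_normal_equations(x, y):
    """(intercept, slope) from the 2x2 normal equations."""
    n = len(x)
    sx = sum(x)
    sxx = sum(v * v for v in x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    det = n * sxx - sx * sx
    intercept = (sxx * sy - sx * sxy) / det
    slope = (n * sxy - sx * sy) / det
    return intercept, slope
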