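"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — exhaustive enumeration and direct
loop arithmetic — and shares no code path with the implementations it
validates.
"""

import math
from collections import Counter
from itertools import combinations


def all_simple_paths(adj, s, t, visited=None):
    """All simple s-t paths in an adjacency dict, by plain DFS."""
    visited = visited or {s}
    if s == t:
        return [[t]]
    paths = []
    for n in sorted(adj[s]):
        if n in visited:
            continue
        for rest in all_simple_paths(adj, n, t, visited | {n}):
            paths.append([s] + rest)
    return paths


def brute_edge_betweenness(edges):
    """Edge betweenness by enumerating every pair's shortest paths."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    eb = {tuple(sorted(e)): 0.0 for e in edges}
    nodes = sorted(adj)
    for s, t in combinations(nodes, 2):
        paths = all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for p in sps:
            for u, v in zip(p, p[1:]):
                eb[tuple(sorted((u, v)))] += 1.0 / len(sps)
    return eb


def brute_modularity(edges, assignment):
    """Q = sum_i (e_ii - a_i^2) by direct counting loops."""
    m = len(edges)
    if m == 0:
        return 0.0
    degree = Counter()
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    q = 0.0
    for cid in set(assignment.values()):
        members = {n for n, c in assignment.items() if c == cid}
        e_ii = sum(1 for u, v in edges if u in members and v in members) / m
        a_i = sum(degree[n] for n in members) / (2 * m)
        q += e_ii - a_i**2
    return q


def set_partitions(items):
    """Every set partition of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def brute_pair_components(statements, level, a, b):
    """(co_support, co_reject, diverge) tallied straight from raw rows."""

    def net(actor):
        per_concept = {}
        for s in statements:
            key = s.organization if level == "organization" else s.person
            if key != actor:
                continue
            per_concept.setdefault(s.concept, [0, 0])
            per_concept[s.concept][0 if s.stance == "agree" else 1] += 1
        return {
            c: (1 if na > nd else -1 if nd > na else 0)
            for c, (na, nd) in per_concept.items()
        }

    na_, nb_ = net(a), net(b)
    cs = cr = dv = 0
    for c in set(na_) & set(nb_):
        sa, sb = na_[c], nb_[c]
        if sa == 1 and sb == 1:
            cs += 1
        elif sa == -1 and sb == -1:
            cr += 1
        elif sa * sb == -1:
            dv += 1
    return cs, cr, dv


def ari_closed_form(labels_a, labels_b):
    """Adjusted Rand index from the contingency table, via math.comb."""
    pairs = list(zip(labels_a, labels_b))
    n = len(pairs)
    cont = Counter(pairs)
    a_sizes = Counter(labels_a)
    b_sizes = Counter(labels_b)
    idx = sum(math.comb(c, 2) for c in cont.values())
    sum_a = sum(math.comb(c, 2) for c in a_sizes.values())
    sum_b = sum(math.comb(c, 2) for c in b_sizes.values())
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    max_idx = (sum_a + sum_b) / 2
    if max_idx == expected:
        return 1.0
    return (idx - expected) / (max_idx - expected)
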