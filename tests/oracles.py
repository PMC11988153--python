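"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, per-sample
scans, double loops — and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- cliques

def brute_force_maximal_cliques(nodes, edges, min_size=2):
    """All maximal cliques by scanning every subset of the node set."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset(p) in edge_set for p in itertools.combinations(sub, 2))

    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not is_clique(sub):
                continue
            others = [v for v in nodes if v not in sub]
            if any(is_clique(sub + (v,)) for v in others):
                continue  # extensible -> not maximal
            cliques.append(tuple(sorted(sub)))
    return sorted(cliques)


# ------------------------------------------------------------- modularity

def double_loop_modularity(weight_matrix, labels):
    """Textbook double-loop Q = (1/2W) sum_ij [A_ij - s_i s_j / 2W] d(c_i, c_j)."""
    a = np.asarray(weight_matrix, dtype=float)
    n = a.shape[0]
    two_w = a.sum()
    if two_w == 0:
        return 0.0
    s = a.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - s[i] * s[j] / two_w
    return q / two_w


def iter_set_partitions(items):
    """All partitions of a list, via restricted-growth strings."""
    items = list(items)
    n = len(items)

    def rec(k, groups):
        if k == n:
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(items[k])
            yield from rec(k + 1, groups)
            g.pop()
        groups.append([items[k]])
        yield from rec(k + 1, groups)
        groups.pop()

    yield from rec(0, [])


def exhaustive_max_modularity(weight_matrix):
    """Maximum Q over every partition of the node set (feasible for n <= 10)."""
    a = np.asarray(weight_matrix, dtype=float)
    n = a.shape[0]
    two_w = a.sum()
    strengths = a.sum(axis=1)
    best = -math.inf
    for parts in iter_set_partitions(range(n)):
        q = 0.0
        for grp in parts:
            idx = np.array(grp)
            q += a[np.ix_(idx, idx)].sum() / two_w - (strengths[idx].sum() / two_w) ** 2
        best = max(best, q)
    return best


# ------------------------------------------------------------ betweenness

def brute_force_betweenness(nodes, weighted_edges):
    """Normalized betweenness by enumerating every simple path (tiny graphs).

    ``weighted_edges``: iterable of (u, v, weight); path length uses 1/weight.
    """
    nodes = list(nodes)
    n = len(nodes)
    adj = {v: {} for v in nodes}
    for u, v, w in weighted_edges:
        adj[u][v] = adj[v][u] = 1.0 / w

    def all_paths(src, dst):
        stack = [(src, [src], 0.0)]
        while stack:
            v, path, dist = stack.pop()
            if v == dst:
                yield path, dist
                continue
            for nb, d in adj[v].items():
                if nb not in path:
                    stack.append((nb, path + [nb], dist + d))

    count = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_paths(s, t))
        if not paths:
            continue
        dmin = min(d for _, d in paths)
        shortest = [p for p, d in paths if abs(d - dmin) < 1e-12]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            count[v] += through / len(shortest)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: c / norm for v, c in count.items()}


# ----------------------------------------------------------------- Mantel

def exact_mantel_p(a, b, alternative="greater"):
    """Exact one-sided Mantel p by enumerating every node relabelling of b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]

    def corr(mat):
        vb = mat[iu]
        return np.corrcoef(va, vb)[0, 1]

    r_obs = corr(b)
    count = total = 0
    for p in itertools.permutations(range(n)):
        perm = np.array(p)
        r = corr(b[np.ix_(perm, perm)])
        total += 1
        if alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += abs(r) >= abs(r_obs) - 1e-12
    return count / total


# ------------------------------------------------------------ bout scans

def per_sample_bout_scan(records, distance_m, gap_tolerance_s, pairing_tol_s):
    """Independent bout reconstruction by a per-dyad, per-sample scan.

    ``records``: DataFrame with animal_id, t, shoulder_x, shoulder_y (already
    filtered to standing and in-window, single pen-day).  Returns a sorted
    list of (animal_a, animal_b, start, end).
    """
    by_animal = {
        a: g.sort_values("t")[["t", "shoulder_x", "shoulder_y"]].to_numpy()
        for a, g in records.groupby("animal_id")
    }
    bouts = []
    animals = sorted(by_animal)
    for a, b in itertools.combinations(animals, 2):
        ta = by_animal[a]
        tb = by_animal[b]
        samples = []  # (t, qualifies)
        for t, xa, ya in ta:
            best = None
            for t2, xb, yb in tb:
                d = abs(t2 - t)
                if best is None or d < best[0]:
                    best = (d, xb, yb)
            if best is not None and best[0] <= pairing_tol_s:
                dist = math.hypot(xa - best[1], ya - best[2])
                samples.append((t, dist <= distance_m))
        cur = []
        prev_idx = None
        for idx, (t, ok) in enumerate(samples):
            if not ok:
                continue
            if cur and (idx != prev_idx + 1 or t - samples[prev_idx][0] > gap_tolerance_s):
                if cur[-1] > cur[0]:
                    bouts.append((a, b, cur[0], cur[-1]))
                cur = []
            cur.append(t)
            prev_idx = idx
        if cur and cur[-1] > cur[0]:
            bouts.append((a, b, cur[0], cur[-1]))
    return sorted(bouts)


# -------------------------------------------------------------- clustering

def pair_enumeration_clustering(nodes, edges):
    """Local clustering by enumerating neighbour pairs."""
    edge_set = {frozenset(e) for e in edges}
    nbrs = {v: set() for v in nodes}
    for e in edge_set:
        u, v = tuple(e)
        nbrs[u].add(v)
        nbrs[v].add(u)
    out = {}
    for v in nodes:
        k = len(nbrs[v])
        if k < 2:
            out[v] = 0.0
            continue
        closed = sum(
            1 for p in itertools.combinations(sorted(nbrs[v]), 2)
            if frozenset(p) in edge_set
        )
        out[v] = closed / (k * (k - 1) / 2)
    return out
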