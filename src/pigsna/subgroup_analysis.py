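"""Subgroup structure: communities, maximal cliques, co-membership, Mantel.

Communities are found by modularity maximization (Louvain) on the weighted
network.  Maximal cliques of the binarized graph (Bron-Kerbosch with
pivoting) describe tight, fully-connected subgroups; counting how often each
dyad shares a clique gives the co-membership matrix, and Mantel permutation
tests quantify how similar co-membership structure is between days or
growing periods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import network_metrics
from .proximity import ContactNetwork
from .tracking_io import PenRoster


@dataclass
class Partition:
    """A node -> community labelling with contiguous integer labels."""

    labels: dict[str, int]
    n_communities: int
    modularity: float

    def communities(self) -> list[tuple[str, ...]]:
        out: dict[int, list[str]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        return [tuple(sorted(out[c])) for c in sorted(out)]


@dataclass
class CliqueSet:
    """Maximal cliques (canonically ordered) of one network."""

    cliques: tuple[tuple[str, ...], ...]
    min_clique_size: int

    @property
    def count(self) -> int:
        return len(self.cliques)

    @property
    def largest_size(self) -> int:
        return max((len(c) for c in self.cliques), default=0)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    method: str = "pearson"
    alternative: str = "greater"
    flagged: bool = False


def _canonical_partition(communities, nodes) -> dict[str, int]:
    comms = sorted((tuple(sorted(c)) for c in communities), key=lambda c: c[0])
    labels = {node: k for k, comm in enumerate(comms) for node in comm}
    missing = set(nodes) - set(labels)
    if missing:
        raise ValueError(f"partition misses node(s): {sorted(missing)}")
    return labels


def _refine_local_moves(g: nx.Graph, labels: dict) -> dict:
    """Greedy single-node moves until no move increases modularity.

    The final polish of the local-move phase, run at node level on the
    un-aggregated graph; deterministic (nodes and target labels visited in
    sorted order, best strictly-improving move taken).
    """
    labels = dict(labels)
    nodes = sorted(g.nodes)
    improved = True
    q_cur = network_metrics.modularity(g, labels)
    while improved:
        improved = False
        for v in nodes:
            candidates = sorted(set(labels.values())) + [max(labels.values()) + 1]
            best_q, best_c = q_cur, labels[v]
            for c in candidates:
                if c == labels[v]:
                    continue
                trial = labels[v]
                labels[v] = c
                q = network_metrics.modularity(g, labels)
                labels[v] = trial
                if q > best_q + 1e-12:
                    best_q, best_c = q, c
            if best_c != labels[v]:
                labels[v] = best_c
                q_cur = best_q
                improved = True
    return labels


def louvain_partition(net, seed: int = 0, n_restarts: int = 8) -> Partition:
    """Louvain community detection on the weighted graph, seeded.

    The local-move order is randomized, so the greedy search is restarted
    ``n_restarts`` times from seeds derived from ``seed`` and the partition
    with the highest modularity is kept (deterministic for a fixed seed).
    An edgeless network yields singleton communities (flagged by warning).
    The reported modularity is recomputed with the package's own Q.
    """
    g = net.graph if isinstance(net, ContactNetwork) else net
    if g.number_of_nodes() < 2:
        raise ValueError("community detection requires at least 2 nodes")
    if g.number_of_edges() == 0:
        warnings.warn("edgeless network: every animal is its own community",
                      stacklevel=2)
        labels = _canonical_partition([{v} for v in g.nodes], g.nodes)
        return Partition(labels=labels, n_communities=len(labels), modularity=0.0)
    best_labels, best_q = None, -np.inf
    for k in range(max(n_restarts, 1)):
        sub_seed = int((int(seed) * 1009 + 7919 * k) % (2**31 - 1))
        comms = nx.community.louvain_communities(g, weight="weight", seed=sub_seed)
        labels = _canonical_partition(comms, g.nodes)
        q = network_metrics.modularity(g, labels)
        if q > best_q:
            best_labels, best_q = labels, q
    best_labels = _refine_local_moves(g, best_labels)
    best_q = network_metrics.modularity(g, best_labels)
    comms = {}
    for v, c in best_labels.items():
        comms.setdefault(c, set()).add(v)
    best_labels = _canonical_partition(comms.values(), g.nodes)
    return Partition(labels=best_labels,
                     n_communities=len(set(best_labels.values())),
                     modularity=best_q)


def maximal_cliques(net, min_clique_size: int = 2) -> CliqueSet:
    """All maximal cliques of the binarized graph with >= min_clique_size members."""
    g = net.graph if isinstance(net, ContactNetwork) else net
    b = nx.Graph()
    b.add_nodes_from(g.nodes)
    b.add_edges_from((u, v) for u, v, d in g.edges(data=True) if d.get("weight", 1) > 0)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(b) if len(c) >= min_clique_size]
    return CliqueSet(cliques=tuple(sorted(cliques)), min_clique_size=min_clique_size)


def co_membership(cliques: CliqueSet, roster) -> pd.DataFrame:
    """Counts of shared maximal-clique memberships per dyad.

    Square integer DataFrame over the roster; the diagonal holds each
    animal's own clique count.
    """
    ids = list(roster.animal_ids if isinstance(roster, PenRoster) else roster)
    index = {a: k for k, a in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=int)
    for clique in cliques.cliques:
        unknown = set(clique) - set(index)
        if unknown:
            raise ValueError(f"clique members outside roster: {sorted(unknown)}")
        idx = [index[a] for a in clique]
        for i in idx:
            m[i, i] += 1
        for i, j in itertools.combinations(idx, 2):
            m[i, j] += 1
            m[j, i] += 1
    return pd.DataFrame(m, index=ids, columns=ids)


def _offdiag_upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].astype(float)


def _rankdata(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x)


def mantel_test(
    a,
    b,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    method: str = "pearson",
) -> MantelResult:
    """Mantel permutation test between two square symmetric matrices.

    The statistic is the Pearson (or Spearman) correlation of the
    off-diagonal upper-triangle entries; the null distribution permutes the
    rows and columns of ``b`` jointly.  p = (1 + #extreme) / (perms + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    n = a.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 items")
    va = _offdiag_upper(a)
    if method == "spearman":
        va = _rankdata(va)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    def stat(mat: np.ndarray) -> float:
        vb = _offdiag_upper(mat)
        if method == "spearman":
            vb = _rankdata(vb)
        if va.std() == 0 or vb.std() == 0:
            return np.nan
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = stat(b)
    if np.isnan(r_obs):
        warnings.warn("zero variance in a matrix: Mantel r undefined", stacklevel=2)
        return MantelResult(np.nan, 1.0, n_permutations, seed, method,
                            alternative, flagged=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        r_perm = stat(b[np.ix_(p, p)])
        if np.isnan(r_perm):
            continue
        if alternative == "greater":
            count += r_perm >= r_obs
        elif alternative == "two-sided":
            count += abs(r_perm) >= abs(r_obs)
        elif alternative == "less":
            count += r_perm <= r_obs
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p_val = (1.0 + count) / (n_permutations + 1.0)
    return MantelResult(r_obs, p_val, n_permutations, seed, method, alternative)


def summarize_subgroups(per_day: pd.DataFrame) -> pd.DataFrame:
    """Per-period Mean (SD) of communities / cliques / largest-clique size.

    ``per_day`` must hold one row per pen-day with columns ``pen_id, period,
    day, n_communities, n_maximal_cliques, largest_clique_size``.
    """
    value_cols = ["n_communities", "n_maximal_cliques", "largest_clique_size"]
    missing = set(value_cols + ["pen_id", "period", "day"]) - set(per_day.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    long = per_day.melt(id_vars=["pen_id", "period", "day"], value_vars=value_cols,
                        var_name="trait", value_name="value")
    return (
        long.groupby(["pen_id", "period", "trait"])["value"]
        .agg(mean="mean", sd="std", max="max", min="min")
        .reset_index()
    )
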