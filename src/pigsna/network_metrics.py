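"""Individual and group-level social-network traits of a contact network.

Conventions
-----------
* degree centrality, density, clustering and all centralizations are computed
  on the *binarized* graph (an edge exists iff any qualifying proximity
  occurred);
* closeness and betweenness run shortest paths on edge lengths ``1/weight``
  (strong proximity = short social distance), falling back to unit lengths on
  the binarized graph when ``weighted=False``;
* eigenvector centrality uses the weight matrix and is scaled to max 1.

Group centralization follows Freeman's index: the sum of (C_max - C_i) over
nodes, normalized by the same sum on the most centralized graph of equal
size — the star for degree/closeness/betweenness, and the one-hot score
vector for eigenvector.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .proximity import ContactNetwork

CENTRALITY_KINDS = ("degree", "closeness", "betweenness", "eigenvector")


def _as_graph(net) -> tuple[nx.Graph, int]:
    g = net.graph if isinstance(net, ContactNetwork) else net
    return g, g.number_of_nodes()


def _binary(g: nx.Graph) -> nx.Graph:
    b = nx.Graph()
    b.add_nodes_from(g.nodes)
    b.add_edges_from((u, v) for u, v, d in g.edges(data=True) if d.get("weight", 1) > 0)
    return b


def _with_lengths(g: nx.Graph) -> nx.Graph:
    h = g.copy()
    for _, _, d in h.edges(data=True):
        d["length"] = 1.0 / d["weight"] if d.get("weight", 0) > 0 else 1.0
    return h


def _eigenvector_scores(g: nx.Graph, weighted: bool) -> dict:
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight" if weighted else None)
    if not a.any():
        return {v: 0.0 for v in nodes}
    vals, vecs = np.linalg.eigh(a)
    lead = np.abs(vecs[:, np.argmax(vals)])
    lead = lead / lead.max()
    return dict(zip(nodes, lead.tolist()))


def node_centrality(net, kind: str, weighted: bool | None = None) -> dict:
    """Per-animal centrality of the given kind.

    ``weighted=None`` applies the default convention per kind (see module
    docstring).  Graphs with fewer than 3 nodes are rejected.
    """
    g, n = _as_graph(net)
    if n < 3:
        raise ValueError("centralities require at least 3 nodes")
    if kind == "degree":
        return nx.degree_centrality(_binary(g) if weighted in (None, False) else g)
    if kind == "closeness":
        if weighted is None or weighted:
            return nx.closeness_centrality(_with_lengths(g), distance="length")
        return nx.closeness_centrality(_binary(g))
    if kind == "betweenness":
        if weighted is None or weighted:
            return nx.betweenness_centrality(_with_lengths(g), weight="length",
                                             normalized=True)
        return nx.betweenness_centrality(_binary(g), normalized=True)
    if kind == "eigenvector":
        return _eigenvector_scores(g, weighted in (None, True))
    raise ValueError(f"unknown centrality kind {kind!r}")


def clustering_coefficient(net) -> dict:
    """Binary local clustering: closed neighbour pairs / possible pairs."""
    g, _ = _as_graph(net)
    return nx.clustering(_binary(g))


def _star_graph_like(n: int) -> nx.Graph:
    g = nx.star_graph(n - 1)
    for _, _, d in g.edges(data=True):
        d["weight"] = 1.0
    return g


def centralization(net, kind: str, weighted: bool = False) -> float:
    """Freeman group centralization of a centrality kind, in [0, 1].

    Numerator: sum of (C_max - C_i) over the network's nodes (binarized
    graph by default).  Denominator: the same sum evaluated on the
    maximally centralized configuration with the same number of nodes —
    computed empirically on the star graph for degree, closeness and
    betweenness, and on the one-hot vector (one node at 1, rest 0) for
    eigenvector.
    """
    if kind not in CENTRALITY_KINDS:
        raise ValueError(f"unknown centrality kind {kind!r}")
    g, n = _as_graph(net)
    if n < 3:
        raise ValueError("centralization requires at least 3 nodes")
    use = g if weighted else _binary(g)
    scores = np.array(list(node_centrality(use, kind, weighted=weighted).values()))
    numer = float(np.sum(scores.max() - scores))
    if kind == "eigenvector":
        denom = float(n - 1)  # one-hot maximizer with max-normalized scores
    else:
        star = _star_graph_like(n)
        sstar = np.array(list(node_centrality(star, kind, weighted=weighted).values()))
        denom = float(np.sum(sstar.max() - sstar))
    return numer / denom if denom > 0 else 0.0


def density(net) -> float:
    """Edge count over n(n-1)/2 on the binarized graph."""
    g, n = _as_graph(net)
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return nx.density(_binary(g))


def modularity(net, partition: Mapping) -> float:
    """Newman's weighted modularity Q of a node -> community mapping.

    Q = sum_c [ W_c / W  -  (S_c / 2W)^2 ]  with W the total edge weight,
    W_c the weight inside community c and S_c the summed node strengths.
    Returns 0 for an edgeless network (flat partition baseline).
    """
    g, _ = _as_graph(net)
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition misses node(s): {sorted(missing)}")
    nodes = list(g.nodes)
    labels = np.array([partition[v] for v in nodes])
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    two_w = a.sum()
    if two_w == 0:
        return 0.0
    same = labels[:, None] == labels[None, :]
    w_in = a[same].sum() / 2.0  # each within-edge counted twice in `a`
    strengths = a.sum(axis=1)
    s_c = np.array([strengths[labels == c].sum() for c in np.unique(labels)])
    w = two_w / 2.0
    return float(w_in / w - np.sum((s_c / (2.0 * w)) ** 2))


def individual_traits(net: ContactNetwork) -> pd.DataFrame:
    """Long-format per-animal trait table for one pen-day network."""
    traits = {kind: node_centrality(net, kind) for kind in CENTRALITY_KINDS}
    traits["clustering_coefficient"] = clustering_coefficient(net)
    rows = [
        {
            "pen_id": net.pen_id,
            "period": net.period,
            "day": net.day,
            "level": "individual",
            "animal_id": animal,
            "trait": f"{kind}_centrality" if kind in CENTRALITY_KINDS else kind,
            "value": float(val),
        }
        for kind, mapping in traits.items()
        for animal, val in mapping.items()
    ]
    return pd.DataFrame(rows)


def group_traits(net: ContactNetwork, partition: Mapping) -> pd.DataFrame:
    """Long-format group-level trait table (centralizations, density, Q)."""
    values = {f"{k}_centralization": centralization(net, k) for k in CENTRALITY_KINDS}
    values["density"] = density(net)
    values["modularity"] = modularity(net, partition)
    rows = [
        {
            "pen_id": net.pen_id,
            "period": net.period,
            "day": net.day,
            "level": "group",
            "animal_id": "",
            "trait": trait,
            "value": float(val),
        }
        for trait, val in values.items()
    ]
    return pd.DataFrame(rows)


def summarize_traits(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Per-period mean and SD of each trait, combining the daily values."""
    keys = ["pen_id", "period", "level", "trait"]
    agg = (
        trait_table.groupby(keys)["value"]
        .agg(mean="mean", sd="std", max="max", min="min")
        .reset_index()
    )
    return agg
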