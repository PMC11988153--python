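"""Community detection, maximal cliques, co-membership and Mantel tests."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pigsna import (
    AnalysisConfig,
    SimConfig,
    co_membership,
    daily_networks,
    filter_window,
    louvain_partition,
    mantel_test,
    maximal_cliques,
    simulate_pen,
)
from pigsna.network_metrics import modularity
from pigsna.subgroup_analysis import CliqueSet, summarize_subgroups

from conftest import graph_to_network, random_weighted_graph
from oracles import (
    brute_force_maximal_cliques,
    exact_mantel_p,
    exhaustive_max_modularity,
)


class TestLouvain:
    def test_two_disconnected_k4s(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        net = graph_to_network(g)
        part = louvain_partition(net, seed=0)
        assert part.n_communities == 2
        comms = {frozenset(c) for c in part.communities()}
        assert comms == {frozenset(map(str, range(4))),
                         frozenset(map(str, range(4, 8)))}

    def test_complete_graph_single_community(self):
        part = louvain_partition(graph_to_network(nx.complete_graph(6)), seed=0)
        assert part.n_communities == 1

    def test_edgeless_graph_singletons_flagged(self):
        net = graph_to_network(nx.empty_graph(5))
        with pytest.warns(UserWarning, match="edgeless"):
            part = louvain_partition(net, seed=0)
        assert part.n_communities == 5

    def test_deterministic_for_fixed_seed(self):
        g = random_weighted_graph(np.random.default_rng(3), 15, 0.3)
        net = graph_to_network(g)
        p1 = louvain_partition(net, seed=11)
        p2 = louvain_partition(net, seed=11)
        assert p1.labels == p2.labels

    def test_reported_modularity_consistent(self):
        g = random_weighted_graph(np.random.default_rng(4), 12, 0.4)
        net = graph_to_network(g)
        part = louvain_partition(net, seed=5)
        assert part.modularity == pytest.approx(
            modularity(net, part.labels), abs=1e-12)

    def test_near_exhaustive_maximum_small_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(8):
            n = int(rng.integers(5, 9))
            g = random_weighted_graph(rng, n, 0.5)
            if g.number_of_edges() == 0:
                continue
            net = graph_to_network(g)
            part = louvain_partition(net, seed=1)
            best = exhaustive_max_modularity(net.weight_matrix().to_numpy())
            assert part.modularity >= 0.95 * best - 1e-9

    def test_local_optimality_under_single_swaps(self):
        g = random_weighted_graph(np.random.default_rng(7), 14, 0.3)
        net = graph_to_network(g)
        part = louvain_partition(net, seed=2)
        labels = dict(part.labels)
        rng = np.random.default_rng(0)
        nodes = list(labels)
        n_comm = part.n_communities
        better = total = 0
        for _ in range(200):
            v = nodes[rng.integers(len(nodes))]
            new = int(rng.integers(n_comm + 1))
            if new == labels[v]:
                continue
            trial = dict(labels)
            trial[v] = new
            total += 1
            if modularity(net, trial) > part.modularity + 1e-12:
                better += 1
        assert better <= 0.05 * total


class TestMaximalCliques:
    def test_k4_single_clique(self):
        cs = maximal_cliques(graph_to_network(nx.complete_graph(4)))
        assert cs.cliques == (("0", "1", "2", "3"),)
        assert cs.count == 1 and cs.largest_size == 4

    def test_triangle_plus_pendant_edge(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        net = graph_to_network(g)
        cs = maximal_cliques(net, min_clique_size=2)
        assert set(cs.cliques) == {("a", "b", "c"), ("c", "d")}
        oracle = brute_force_maximal_cliques("abcd", g.edges, 2)
        assert sorted(cs.cliques) == oracle

    def test_random_graphs_match_subset_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            g = random_weighted_graph(rng, n, float(rng.uniform(0.3, 0.7)))
            net = graph_to_network(g)
            cs = maximal_cliques(net, min_clique_size=2)
            oracle = brute_force_maximal_cliques(
                [str(v) for v in g.nodes],
                [(str(u), str(v)) for u, v in g.edges], 2)
            assert sorted(cs.cliques) == oracle

    def test_every_clique_passes_independent_predicate(self):
        g = random_weighted_graph(np.random.default_rng(19), 12, 0.45)
        net = graph_to_network(g)
        edges = {frozenset((str(u), str(v))) for u, v in g.edges}
        nodes = [str(v) for v in g.nodes]
        for clique in maximal_cliques(net).cliques:
            assert all(frozenset(p) in edges
                       for p in itertools.combinations(clique, 2))
            for v in set(nodes) - set(clique):
                assert not all(frozenset((v, m)) in edges for m in clique)


class TestCoMembership:
    ROSTER = ("a", "b", "c", "d")

    def test_known_counts(self):
        cs = CliqueSet(cliques=(("a", "b", "c"), ("c", "d")), min_clique_size=2)
        m = co_membership(cs, self.ROSTER)
        assert m.loc["a", "b"] == 1
        assert m.loc["c", "d"] == 1
        assert m.loc["a", "d"] == 0
        assert m.loc["c", "c"] == 2

    def test_empty_clique_set_zero_matrix(self):
        cs = CliqueSet(cliques=(), min_clique_size=2)
        assert (co_membership(cs, self.ROSTER).to_numpy() == 0).all()

    def test_matches_triple_loop_tally(self):
        rng = np.random.default_rng(23)
        roster = [f"p{i}" for i in range(8)]
        cliques = tuple(
            tuple(sorted(rng.choice(roster, size=rng.integers(2, 5), replace=False)))
            for _ in range(6)
        )
        m = co_membership(CliqueSet(cliques, 2), roster)
        for i in roster:
            for j in roster:
                expected = 0
                for c in cliques:
                    if i in c and j in c:
                        expected += 1
                assert m.loc[i, j] == expected

    def test_positive_entry_implies_edge(self):
        g = random_weighted_graph(np.random.default_rng(29), 10, 0.4)
        net = graph_to_network(g)
        cs = maximal_cliques(net)
        m = co_membership(cs, net.roster)
        edges = {frozenset((str(u), str(v))) for u, v in g.edges}
        ids = list(net.roster.animal_ids)
        for i, j in itertools.combinations(ids, 2):
            if m.loc[i, j] > 0:
                assert frozenset((i, j)) in edges

    def test_bounded_by_diagonal(self):
        g = random_weighted_graph(np.random.default_rng(31), 9, 0.5)
        net = graph_to_network(g)
        m = co_membership(maximal_cliques(net), net.roster)
        a = m.to_numpy()
        assert (a == a.T).all()
        d = np.diag(a)
        assert (a <= np.minimum.outer(d, d) + 1e-9).all()


class TestMantel:
    def _sym(self, rng, n=8):
        a = rng.random((n, n))
        a = a + a.T
        np.fill_diagonal(a, 0.0)
        return a

    def test_self_comparison_r_one(self):
        a = self._sym(np.random.default_rng(0))
        res = mantel_test(a, a, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_exact_enumeration_small_roster(self):
        rng = np.random.default_rng(41)
        a = self._sym(rng, 4)
        b = self._sym(rng, 4)
        exact = exact_mantel_p(a, b, "greater")
        res = mantel_test(a, b, n_permutations=4999, seed=3)
        assert res.p == pytest.approx(exact, abs=0.04)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(43)
        a, b = self._sym(rng), self._sym(rng)
        r0 = mantel_test(a, b, n_permutations=99, seed=1).r
        r1 = mantel_test(3.0 * a + 5.0, 0.5 * b + 2.0, n_permutations=99, seed=1).r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_flagged(self):
        a = np.ones((5, 5)); np.fill_diagonal(a, 0.0)
        b = self._sym(np.random.default_rng(2), 5)
        with pytest.warns(UserWarning, match="zero variance"):
            res = mantel_test(a, b, n_permutations=99, seed=0)
        assert res.flagged and np.isnan(res.r)

    def test_p_lower_bound(self):
        a = self._sym(np.random.default_rng(5))
        res = mantel_test(a, a, n_permutations=99, seed=0)
        assert res.p >= 1.0 / (99 + 1)

    def test_spearman_matches_rank_transform(self):
        rng = np.random.default_rng(47)
        a, b = self._sym(rng), self._sym(rng)
        from scipy.stats import rankdata

        iu = np.triu_indices(8, k=1)
        expected = np.corrcoef(rankdata(a[iu]), rankdata(b[iu]))[0, 1]
        res = mantel_test(a, b, n_permutations=99, seed=0, method="spearman")
        assert res.r == pytest.approx(expected)


class TestSummaries:
    def test_single_day_row(self):
        df = pd.DataFrame(
            [{"pen_id": "pen1", "period": "early", "day": 1,
              "n_communities": 3, "n_maximal_cliques": 20,
              "largest_clique_size": 6}]
        )
        out = summarize_subgroups(df)
        means = out.set_index("trait")["mean"]
        assert means["n_communities"] == 3
        assert means["n_maximal_cliques"] == 20
        assert means["largest_clique_size"] == 6

    def test_identical_days_zero_sd(self):
        rows = [{"pen_id": "pen1", "period": "early", "day": d,
                 "n_communities": 4, "n_maximal_cliques": 15,
                 "largest_clique_size": 5} for d in (1, 2, 3)]
        out = summarize_subgroups(pd.DataFrame(rows))
        assert (out["sd"] == 0).all()

    def test_means_match_direct_recomputation(self):
        rng = np.random.default_rng(51)
        rows = [{"pen_id": "pen1", "period": "early", "day": d,
                 "n_communities": int(rng.integers(2, 6)),
                 "n_maximal_cliques": int(rng.integers(10, 30)),
                 "largest_clique_size": int(rng.integers(3, 8))}
                for d in (1, 2, 3)]
        df = pd.DataFrame(rows)
        out = summarize_subgroups(df).set_index("trait")
        for trait in ("n_communities", "n_maximal_cliques", "largest_clique_size"):
            assert out.loc[trait, "mean"] == pytest.approx(df[trait].mean())


def test_planted_groups_recovered_from_network():
    """High-affinity simulation: Louvain and co-membership find the planted split."""
    from sklearn.metrics import adjusted_rand_score

    # full 12 h observation day: short windows leave rarely-standing pigs
    # isolated, which is a sampling artefact rather than a recovery failure
    cfg = SimConfig(n_pigs=14, n_days=1, rng_seed=33, affinity=0.9)
    records, truth = simulate_pen(cfg)
    filtered = filter_window(records, AnalysisConfig())
    nets, _, _ = daily_networks(filtered, cfg.roster(), AnalysisConfig(), "early")
    net = nets[1]
    part = louvain_partition(net, seed=0)
    ids = list(cfg.animal_ids)
    truth_labels = [truth.labels()[a] for a in ids]
    ari = adjusted_rand_score(truth_labels, [part.labels[a] for a in ids])
    assert ari >= 0.9
    m = co_membership(maximal_cliques(net), net.roster)
    within = [m.loc[a, b] for a, b in itertools.combinations(ids, 2)
              if truth.same_group.loc[a, b]]
    between = [m.loc[a, b] for a, b in itertools.combinations(ids, 2)
               if not truth.same_group.loc[a, b]]
    assert np.mean(within) > np.mean(between)
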