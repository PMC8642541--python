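import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modcrn import modcluster
from modcrn.degcall import call_degs
from modcrn.modcluster import (
    ClusterPartition,
    betweenness_ranking,
    cluster_expression_profile,
    cluster_geneset_enrichment,
    cluster_proteins,
    combine_modules,
    gtom_dissimilarity,
)
from modcrn.modisco import RegulatoryModule
from tests.conftest import two_organ_meta


def mk_module(nodes, edges, organ):
    return RegulatoryModule(frozenset(nodes), frozenset(tuple(sorted(e)) for e in edges), organ, 1)


class TestCombineModules:
    def test_idempotent(self):
        m = mk_module("abc", [("a", "b")], "lung")
        combined = combine_modules([m, m])
        assert combined.nodes == m.nodes and combined.edges == m.edges
        assert all(v == "lung" for v in combined.membership.values())
        assert combined.n_shared == 0  # same organ twice is not cross-organ sharing

    def test_disjoint_modules(self):
        a = mk_module("abc", [("a", "b")], "lung")
        b = mk_module("xyz", [("x", "y")], "liver")
        combined = combine_modules([a, b])
        assert len(combined.nodes) == 6 and combined.n_shared == 0

    def test_shared_node_flagged_both(self):
        a = mk_module("abc", [("a", "b"), ("b", "c")], "lung")
        b = mk_module("cde", [("c", "d"), ("d", "e")], "liver")
        combined = combine_modules([a, b])
        assert combined.n_shared == 1
        assert combined.membership["c"] == "both"
        assert combined.edges == a.edges | b.edges  # set-algebra oracle
        # commutative
        assert combine_modules([b, a]).nodes == combined.nodes

    def test_attaches_per_organ_log2fc(self):
        meta = two_organ_meta(2)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(8, 1, (3, len(meta))), index=list("abc"), columns=meta.index)
        degs = {o: call_degs(expr, meta, o) for o in ("liver", "lung")}
        a = mk_module("ab", [("a", "b")], "lung")
        b = mk_module("bc", [("b", "c")], "liver")
        combined = combine_modules([a, b], deg_results=degs)
        assert set(combined.log2fc["b"]) == {"liver", "lung"}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_modules([])


class TestGTOM:
    def test_complete_graph_overlap_is_one(self):
        for n in (2, 4, 7):
            nodes = [f"n{i}" for i in range(n)]
            edges = set(itertools.combinations(nodes, 2))
            d = gtom_dissimilarity(nodes, edges)
            # closed form: l = n-2, a = 1, min k = n-1 -> t = 1 -> d = 0
            assert np.allclose(d.to_numpy(), 0.0)

    def test_path_graph_hand_computation(self):
        d = gtom_dissimilarity(["a", "b", "c"], {("a", "b"), ("b", "c")})
        # t_ac = (1+0)/(1+1-0) = 0.5 ; t_ab = (0+1)/(1+1-1) = 1
        assert d.loc["a", "c"] == pytest.approx(0.5)
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["b", "c"] == pytest.approx(0.0)

    def test_order_two_uses_two_step_reachability(self):
        # path a-b-c-d-e: within 2 steps a reaches {b,c}, e reaches {c,d}
        nodes = list("abcde")
        edges = {("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")}
        d2 = gtom_dissimilarity(nodes, edges, m=2)
        a2 = np.zeros((5, 5))
        g = nx.Graph(sorted(edges))
        sp = dict(nx.all_pairs_shortest_path_length(g))
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if u != v and sp[u].get(v, 99) <= 2:
                    a2[i, j] = 1
        k = a2.sum(1)
        l = a2 @ a2
        expected = 1 - (l + a2) / (np.minimum.outer(k, k) + 1 - a2)
        np.fill_diagonal(expected, 0)
        assert np.allclose(d2.to_numpy(), expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_graph_invariants(self, seed):
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        nodes = [f"n{i}" for i in g.nodes]
        edges = {(f"n{u}", f"n{v}") for u, v in g.edges}
        d = gtom_dissimilarity(nodes, edges).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_permutation_equivariance(self):
        nodes = list("abcdef")
        rng = np.random.default_rng(3)
        edges = {tuple(sorted(e)) for e in itertools.combinations(nodes, 2) if rng.random() < 0.5}
        d = gtom_dissimilarity(nodes, edges)
        renamed = {n: f"z{n}" for n in nodes}
        d2 = gtom_dissimilarity(
            [renamed[n] for n in nodes], {(renamed[u], renamed[v]) for u, v in edges}
        )
        for u, v in itertools.combinations(nodes, 2):
            assert d.loc[u, v] == pytest.approx(d2.loc[renamed[u], renamed[v]])

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            gtom_dissimilarity(["a", "b"], {("a", "b")}, m=0)


def two_cliques_bridge():
    """Two 4-cliques joined by one bridge edge."""
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    edges = set(itertools.combinations(a, 2)) | set(itertools.combinations(b, 2))
    edges.add(("a0", "b0"))
    return a + b, {tuple(sorted(e)) for e in edges}


class TestClusterProteins:
    def test_two_cliques_with_bridge_separate_at_k2(self):
        nodes, edges = two_cliques_bridge()
        d = gtom_dissimilarity(nodes, edges)
        part = cluster_proteins(d, k=2)
        got = {frozenset(m) for m in part.clusters.values()}
        # oracle: exhaustive 2-partition minimizing total within-cluster dissimilarity
        best, best_cost = None, np.inf
        ns = list(d.index)
        for mask in range(1, 2 ** (len(ns) - 1)):
            left = frozenset(n for i, n in enumerate(ns) if (mask >> i) & 1 or i == len(ns) - 1 and False)
            left = frozenset(n for i, n in enumerate(ns) if (mask >> i) & 1)
            right = frozenset(ns) - left
            if not left or not right:
                continue
            cost = sum(d.loc[u, v] for grp in (left, right) for u, v in itertools.combinations(sorted(grp), 2))
            if cost < best_cost:
                best, best_cost = {left, right}, cost
        assert got == best
        assert got == {frozenset(f"a{i}" for i in range(4)), frozenset(f"b{i}" for i in range(4))}

    def test_k_equals_n_gives_singletons(self):
        nodes, edges = two_cliques_bridge()
        d = gtom_dissimilarity(nodes, edges)
        part = cluster_proteins(d, k=len(nodes))
        assert part.n_clusters == len(nodes)
        assert all(len(m) == 1 for m in part.clusters.values())

    def test_k_one_gives_single_cluster(self):
        nodes, edges = two_cliques_bridge()
        part = cluster_proteins(gtom_dissimilarity(nodes, edges), k=1)
        assert part.n_clusters == 1
        assert part.clusters[1] == frozenset(nodes)

    def test_silhouette_default_recovers_planted_split(self):
        nodes, edges = two_cliques_bridge()
        part = cluster_proteins(gtom_dissimilarity(nodes, edges))
        assert {frozenset(m) for m in part.clusters.values()} == {
            frozenset(f"a{i}" for i in range(4)),
            frozenset(f"b{i}" for i in range(4)),
        }

    def test_partition_is_disjoint_cover_for_every_k(self):
        nodes, edges = two_cliques_bridge()
        d = gtom_dissimilarity(nodes, edges)
        for k in range(1, len(nodes) + 1):
            part = cluster_proteins(d, k=k)
            members = [n for m in part.clusters.values() for n in m]
            assert sorted(members) == sorted(nodes)
            assert sorted(part.clusters) == list(range(1, part.n_clusters + 1))

    def test_k_exceeding_n_rejected(self):
        d = gtom_dissimilarity(["a", "b"], {("a", "b")})
        with pytest.raises(ValueError):
            cluster_proteins(d, k=3)


class TestClusterExpression:
    def make(self, clusters, values, samples=None):
        part = ClusterPartition({i + 1: frozenset(m) for i, m in enumerate(clusters)})
        genes = sorted({g for m in clusters for g in m})
        samples = samples or [f"s{i}" for i in range(len(values[0]))]
        expr = pd.DataFrame(values, index=genes, columns=samples)
        return part, expr

    def test_singleton_cluster_profile_equals_gene_row(self):
        part, expr = self.make([["g1"]], [[1.0, 2.0, 3.0]])
        ce = cluster_expression_profile(part, expr)
        assert (ce.profile.loc[1] == expr.loc["g1"]).all()

    def test_median_odd_and_even_counts(self):
        part, expr = self.make([["g1", "g2", "g3"]], [[1.0], [2.0], [9.0]])
        assert cluster_expression_profile(part, expr).profile.iloc[0, 0] == 2.0
        part, expr = self.make([["g1", "g2", "g3", "g4"]], [[1.0], [2.0], [3.0], [10.0]])
        assert cluster_expression_profile(part, expr).profile.iloc[0, 0] == 2.5

    def test_scaled_rows_standardized(self):
        rng = np.random.default_rng(1)
        part, expr = self.make([["g1", "g2"], ["g3"]], rng.normal(8, 1, (3, 6)).tolist())
        ce = cluster_expression_profile(part, expr)
        assert np.allclose(ce.scaled.mean(axis=1), 0.0)
        assert np.allclose(ce.scaled.std(axis=1, ddof=1), 1.0)

    def test_commutes_with_sample_permutation(self):
        rng = np.random.default_rng(2)
        part, expr = self.make([["g1", "g2", "g3"]], rng.normal(size=(3, 5)).tolist())
        ce = cluster_expression_profile(part, expr)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        ce_p = cluster_expression_profile(part, expr[perm])
        assert (ce.profile[perm].to_numpy() == ce_p.profile.to_numpy()).all()

    def test_missing_members_warn_or_error(self):
        part = ClusterPartition({1: frozenset({"g1", "ghost"}), 2: frozenset({"gone"})})
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s0", "s1"])
        with pytest.raises(ValueError, match="cluster 2"):
            cluster_expression_profile(part, expr)
        part1 = ClusterPartition({1: frozenset({"g1", "ghost"})})
        with pytest.warns(UserWarning, match="cluster 1"):
            ce = cluster_expression_profile(part1, expr)
        assert (ce.profile.loc[1] == expr.loc["g1"]).all()


class TestBetweenness:
    def test_path_graph(self):
        t = betweenness_ranking(["a", "b", "c"], {("a", "b"), ("b", "c")})
        assert t.iloc[0]["protein"] == "b" and t.iloc[0]["betweenness"] == 1.0
        assert set(t[t["betweenness"] == 0]["protein"]) == {"a", "c"}

    def test_star_center_scores_pair_count(self):
        leaves = [f"l{i}" for i in range(4)]
        t = betweenness_ranking(["c"] + leaves, {("c", l) for l in leaves})
        assert t.iloc[0]["protein"] == "c" and t.iloc[0]["betweenness"] == 6.0

    def test_complete_graph_all_zero_lexicographic(self):
        nodes = list("dcba")
        t = betweenness_ranking(nodes, set(itertools.combinations(sorted(nodes), 2)))
        assert (t["betweenness"] == 0).all()
        assert list(t["protein"]) == sorted(nodes)

    def test_matches_exhaustive_path_enumeration(self):
        g = nx.gnp_random_graph(9, 0.35, seed=11)
        nodes = [str(n) for n in g.nodes]
        edges = {(str(u), str(v)) for u, v in g.edges}
        t = betweenness_ranking(nodes, edges).set_index("protein")["betweenness"]
        # oracle: count shortest paths through each node by brute force
        expected = dict.fromkeys(nodes, 0.0)
        for s, u in itertools.combinations(nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(nx.Graph(sorted(edges)), s, u))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for mid in path[1:-1]:
                    expected[mid] += 1 / len(paths)
        for n in nodes:
            assert t[n] == pytest.approx(expected[n])


class TestGenesetEnrichment:
    def test_cluster_identical_to_set_is_top_hit(self):
        part = ClusterPartition({1: frozenset({"a", "b", "c"}), 2: frozenset({"x", "y"})})
        bg = {f"g{i}" for i in range(50)} | {"a", "b", "c", "x", "y"}
        sets = {"hit": {"a", "b", "c"}, "other": {"g1", "g2", "g3"}}
        table = cluster_geneset_enrichment(part, sets, bg)
        best = table.sort_values("p").iloc[0]
        assert best["cluster"] == 1 and best["gene_set"] == "hit"
        assert best["overlap"] == 3

    def test_disjoint_set_gives_p_one(self):
        part = ClusterPartition({1: frozenset({"a", "b"})})
        bg = {"a", "b", "c", "d", "e", "f"}
        table = cluster_geneset_enrichment(part, {"s": {"c", "d"}}, bg)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_single_test_bh_equals_raw(self):
        part = ClusterPartition({1: frozenset({"a", "b"})})
        bg = {"a", "b", "c", "d", "e", "f"}
        table = cluster_geneset_enrichment(part, {"s": {"a", "c"}}, bg)
        assert table["p_adj"].iloc[0] == pytest.approx(table["p"].iloc[0])

    def test_bh_adjustment_bounds(self):
        part = ClusterPartition({1: frozenset({"a", "b"}), 2: frozenset({"c", "d"})})
        bg = {chr(97 + i) for i in range(20)}
        sets = {"s1": {"a", "b"}, "s2": {"e", "f"}, "s3": {"c", "q"}}
        table = cluster_geneset_enrichment(part, sets, bg)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        assert table["p_adj"].between(0, 1).all()

    def test_empty_geneset_rejected(self):
        part = ClusterPartition({1: frozenset({"a"})})
        with pytest.raises(ValueError, match="empty"):
            cluster_geneset_enrichment(part, {"s": set()}, {"a", "b"})
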