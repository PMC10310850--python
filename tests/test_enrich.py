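"""GSEA scoring, similarity networks, graph metrics and over-representation."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ffed import enrich


def oracle_ks_walk(genes, scores, members, exponent):
    """Independent step-by-step evaluation of the weighted KS running sum."""
    n = len(genes)
    hits = [g in members for g in genes]
    weights = [abs(s) ** exponent if h else 0.0 for s, h in zip(scores, hits)]
    total = sum(weights) or float(sum(hits))
    if sum(weights) == 0:
        weights = [1.0 if h else 0.0 for h in hits]
    miss = 1.0 / (n - sum(hits))
    walk, acc = [], 0.0
    for w, h in zip(weights, hits):
        acc += w / total if h else -miss
        walk.append(acc)
    es = max(walk, key=abs)
    return es, walk


class TestGseaES:
    def test_top_k_set_peaks_at_rank_k(self):
        ranked = [(f"g{i}", 10.0 - i) for i in range(10)]
        es, running = enrich.gsea_es(ranked, {"g0", "g1", "g2"})
        assert es > 0
        assert np.argmax(running) == 2

    def test_matches_exhaustive_walk_on_all_small_sets(self):
        """Every 1- and 2-gene subset of a 5-gene list, exponent 0 and 1."""
        ranked = [("a", 3.0), ("b", 2.0), ("c", 1.0), ("d", -1.5), ("e", -4.0)]
        genes = [g for g, _ in ranked]
        scores = [s for _, s in ranked]
        for k in (1, 2):
            for members in itertools.combinations(genes, k):
                for expo in (0.0, 1.0):
                    es, running = enrich.gsea_es(ranked, set(members), expo)
                    o_es, o_walk = oracle_ks_walk(genes, scores, set(members), expo)
                    assert np.isclose(es, o_es)
                    assert np.allclose(running, o_walk)

    def test_reversed_list_negates_unweighted_es(self):
        ranked = [(f"g{i}", 5.0 - i) for i in range(6)]
        rev = [(g, -s) for g, s in reversed(ranked)]
        members = {"g0", "g1"}
        es_f, _ = enrich.gsea_es(ranked, members, exponent=0)
        es_r, _ = enrich.gsea_es(rev, members, exponent=0)
        assert np.isclose(es_f, -es_r)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance_at_exponent_zero(self, c):
        ranked = [("a", 3.0), ("b", 2.0), ("c", 1.0), ("d", 0.5), ("e", 0.1)]
        scaled = [(g, c * s) for g, s in ranked]
        es1, _ = enrich.gsea_es(ranked, {"a", "c"}, exponent=0)
        es2, _ = enrich.gsea_es(scaled, {"a", "c"}, exponent=0)
        assert np.isclose(es1, es2)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            enrich.gsea_es([("a", 1.0)], {"zzz"})


@pytest.fixture(scope="module")
def random_ranking():
    rng = np.random.default_rng(0)
    scores = np.sort(rng.normal(size=400))[::-1]
    return [(f"g{i}", s) for i, s in enumerate(scores)]


class TestGseaSignificance:
    def test_spiked_set_significant(self, random_ranking):
        top = {g for g, _ in random_ranking[:25]}
        collection = {"spiked": top}
        rng = np.random.default_rng(1)
        genes = [g for g, _ in random_ranking]
        for i in range(9):
            collection[f"rand{i}"] = set(rng.choice(genes, 25, replace=False))
        res = enrich.gsea_significance(random_ranking, collection, n_perm=1000, seed=2)
        assert res.loc["spiked", "q"] < 0.05
        assert res.loc["spiked", "direction"] == "up"

    def test_random_sets_mostly_null(self, random_ranking):
        rng = np.random.default_rng(3)
        genes = [g for g, _ in random_ranking]
        collection = {
            f"r{i}": set(rng.choice(genes, 20, replace=False)) for i in range(40)
        }
        res = enrich.gsea_significance(random_ranking, collection, n_perm=200, seed=4)
        assert (res["pvalue"] < 0.05).mean() <= 0.15
        assert res["q"].max() > 0.3  # q spread broadly, not collapsed

    def test_sign_consistency_and_q_range(self, random_ranking):
        collection = {
            "top": {g for g, _ in random_ranking[:15]},
            "bottom": {g for g, _ in random_ranking[-15:]},
        }
        res = enrich.gsea_significance(random_ranking, collection, n_perm=300, seed=5)
        assert np.sign(res["NES"]).equals(np.sign(res["ES"]).astype(float))
        assert res["q"].between(0, 1).all()

    def test_seed_determinism(self, random_ranking):
        collection = {"top": {g for g, _ in random_ranking[:15]}}
        a = enrich.gsea_significance(random_ranking, collection, n_perm=100, seed=7)
        b = enrich.gsea_significance(random_ranking, collection, n_perm=100, seed=7)
        pd.testing.assert_frame_equal(a, b)


def results_frame(qs, direction="up"):
    return pd.DataFrame(
        {"q": qs, "direction": direction, "ES": 1.0, "NES": 1.0},
        index=[f"set{i}" for i in range(len(qs))],
    )


class TestSimilarityNetwork:
    def test_disjoint_sets_no_edge(self):
        coll = {"set0": {"a", "b"}, "set1": {"c", "d"}}
        net = enrich.build_similarity_network(results_frame([0.01, 0.01]), coll)
        assert net.number_of_edges() == 0

    def test_identical_sets_similarity_one(self):
        coll = {"set0": {"a", "b"}, "set1": {"a", "b"}}
        net = enrich.build_similarity_network(results_frame([0.01, 0.01]), coll)
        assert net["set0"]["set1"]["similarity"] == 1.0

    def test_hand_computed_combined_coefficients(self):
        # set0={a,b,c,d}, set1={c,d,e,f}: J=2/6, O=2/4 -> 0.41666
        # set0 vs set2={a,b,c}: J=3/4, O=3/3 -> 0.875
        coll = {
            "set0": {"a", "b", "c", "d"},
            "set1": {"c", "d", "e", "f"},
            "set2": {"a", "b", "c"},
        }
        net = enrich.build_similarity_network(
            results_frame([0.01, 0.01, 0.01]), coll, cutoff=0.375
        )
        assert np.isclose(net["set0"]["set1"]["similarity"], 0.5 * (2 / 6) + 0.5 * 0.5)
        assert np.isclose(net["set0"]["set2"]["similarity"], 0.5 * 0.75 + 0.5 * 1.0)

    def test_no_significant_sets_gives_empty_network(self):
        """The explicit 'no network' outcome when nothing passes the q cut."""
        coll = {"set0": {"a"}, "set1": {"b"}}
        net = enrich.build_similarity_network(results_frame([0.5, 0.9]), coll)
        assert net.number_of_nodes() == 0
        metrics = enrich.network_metrics(net)
        assert metrics.total_nodes == 0 and metrics.diameter == 0.0


def oracle_metrics(net):
    """All-pairs BFS diameter, per-node triangle clustering, direct counts."""
    nodes = list(net.nodes)
    n, e = len(nodes), net.number_of_edges()
    comps, seen = [], set()
    for start in nodes:
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in net.neighbors(u):
                    if v not in comp:
                        comp.add(v)
                        nxt.append(v)
            frontier = nxt
        comps.append(comp)
        seen |= comp
    largest = max(comps, key=len)
    diameter = 0
    for src in largest:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in net.neighbors(u):
                    if v in largest and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        diameter = max(diameter, max(dist.values()))
    local = []
    for u in nodes:
        nbrs = list(net.neighbors(u))
        k = len(nbrs)
        if k < 2:
            local.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if net.has_edge(a, b)
        )
        local.append(2 * links / (k * (k - 1)))
    return {
        "total_nodes": n,
        "total_edges": e,
        "diameter": float(diameter),
        "density": 2 * e / (n * (n - 1)) if n > 1 else 0.0,
        "clustering_coefficient": float(np.mean(local)) if local else 0.0,
        "average_degree": 2 * e / n if n else 0.0,
    }


class TestNetworkMetrics:
    def test_triangle(self):
        m = enrich.network_metrics(nx.complete_graph(3))
        assert (m.diameter, m.clustering_coefficient, m.average_degree, m.density) == (
            1.0, 1.0, 2.0, 1.0,
        )

    def test_path_of_three(self):
        m = enrich.network_metrics(nx.path_graph(3))
        assert m.diameter == 2.0
        assert m.clustering_coefficient == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graph_matches_brute_force_oracle(self, seed):
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        m = enrich.network_metrics(g)
        o = oracle_metrics(g)
        for key, val in o.items():
            assert np.isclose(getattr(m, key), val), key


class TestClusters:
    def test_single_component_single_cluster(self):
        g = nx.path_graph(4)
        assert len(enrich.summarize_clusters(g)) == 1

    def test_empty_network_empty_list(self):
        assert enrich.summarize_clusters(nx.Graph()) == []

    def test_two_cliques_match_component_oracle(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(4))
        g = nx.relabel_nodes(g, {i: f"axon guidance {i}" if i < 3 else f"synapse assembly {i}" for i in g.nodes})
        clusters = enrich.summarize_clusters(g)
        assert len(clusters) == 2
        sizes = sorted(len(c["members"]) for c in clusters)
        assert sizes == [3, 4]
        labels = {c["label"] for c in clusters}
        assert any("axon" in l for l in labels)
        assert any("synapse" in l for l in labels)


def oracle_hypergeom_tail(N, K, n, k):
    """Exact tail by direct combinatorial summation."""
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        for x in range(k, min(n, K) + 1)
    )


class TestHypergeom:
    def test_matches_enumeration_at_small_n(self):
        background = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(6)}
        hits = {"g0", "g1", "g2", "g10"}
        res = enrich.hypergeom_enrichment(hits, target, background)
        assert np.isclose(res["pvalue"], oracle_hypergeom_tail(20, 6, 4, 3))

    def test_all_hits_in_target_product_form(self):
        background = {f"g{i}" for i in range(15)}
        target = {f"g{i}" for i in range(5)}
        hits = {"g0", "g1", "g2"}
        res = enrich.hypergeom_enrichment(hits, target, background)
        assert np.isclose(res["pvalue"], oracle_hypergeom_tail(15, 5, 3, 3))

    def test_disjoint_target_p_one(self):
        background = {"a", "b", "c", "d"}
        assert enrich.hypergeom_enrichment({"a"}, {"zzz"}, background)["pvalue"] == 1.0

    def test_hits_equal_background_p_one(self):
        background = {"a", "b", "c"}
        res = enrich.hypergeom_enrichment(background, {"a", "b"}, background)
        assert np.isclose(res["pvalue"], 1.0)

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            enrich.hypergeom_enrichment({"x"}, {"a"}, {"a", "b"})
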