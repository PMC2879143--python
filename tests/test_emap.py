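"""Enrichment Map construction, layout, summarization, and export."""

import numpy as np
import pytest

from protmap.emap import (
    EnrichmentMapGraph,
    build_map,
    export_graph,
    import_tables,
    layout,
    overlap_coefficient,
    render,
    summarize_cluster_terms,
)
from protmap.genesets import GeneSet, GeneSetCollection
from protmap.gsea import EnrichmentResult
from protmap.quantify import InputError


def result(name, es=0.8, p=0.001, q=0.01, size=20):
    return EnrichmentResult(
        set_name=name, set_size_effective=size, ES=es, NES=2.0 * np.sign(es),
        p_nominal=p, fdr_q=q, direction="up" if es > 0 else "down",
        leading_edge=frozenset(),
    )


def genes(a, b):
    return frozenset(f"g{i}" for i in range(a, b))


class TestOverlapCoefficient:
    def test_subset_saturates(self):
        assert overlap_coefficient(genes(0, 5), genes(0, 20)) == 1.0

    def test_disjoint_sets(self):
        assert overlap_coefficient(genes(0, 5), genes(5, 10)) == 0.0

    def test_partial_overlap(self):
        a, b = genes(0, 10), genes(4, 24)
        assert overlap_coefficient(a, b) == 0.6

    def test_symmetry_and_jaccard_bound(self, rng):
        for _ in range(50):
            a = frozenset(rng.choice(40, rng.integers(1, 20), replace=False))
            b = frozenset(rng.choice(40, rng.integers(1, 20), replace=False))
            ov = overlap_coefficient(a, b)
            assert ov == overlap_coefficient(b, a)
            jaccard = len(a & b) / len(a | b)
            assert ov >= jaccard

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            overlap_coefficient(set(), genes(0, 5))


def make_collection(memberships: dict[str, frozenset]):
    universe = frozenset().union(*memberships.values())
    return GeneSetCollection(
        sets=[GeneSet(n, f"{n} desc", m) for n, m in memberships.items()],
        universe=set(universe),
    )


class TestBuildMap:
    def test_nothing_significant_gives_empty_graph(self):
        coll = make_collection({"a": genes(0, 20)})
        g = build_map([result("a", p=0.5, q=0.9)], coll)
        assert g.graph.number_of_nodes() == 0
        assert g.graph.number_of_edges() == 0

    def test_identical_membership_pair(self):
        coll = make_collection({"a": genes(0, 20), "b": genes(0, 20)})
        g = build_map([result("a"), result("b")], coll)
        assert g.graph.number_of_nodes() == 2
        (edge,) = g.edges()
        assert edge.overlap == 1.0 and edge.n_shared == 20

    def test_edge_rule_is_strictly_greater(self):
        """Hand-authored overlaps 0.2 / 0.5 / 0.6 / 1.0: only the strict
        >0.5 pairs are linked, so 0.5 itself draws no edge."""
        memberships = {
            "a": genes(0, 10),
            "b": genes(8, 18),    # ov(a,b) = 2/10 = 0.2
            "c": genes(5, 15),    # ov(a,c) = 5/10 = 0.5
            "d": genes(4, 14),    # ov(a,d) = 6/10 = 0.6
            "e": genes(0, 10),    # ov(a,e) = 1.0
        }
        coll = make_collection(memberships)
        g = build_map([result(n) for n in memberships], coll)
        edges = {(e.set_a, e.set_b) for e in g.edges()}
        assert ("a", "c") not in edges
        assert ("a", "d") in edges
        assert ("a", "e") in edges

    def test_raising_threshold_only_prunes(self):
        memberships = {
            "a": genes(0, 10), "b": genes(4, 14), "c": genes(2, 12),
        }
        coll = make_collection(memberships)
        results = [result(n) for n in memberships]
        lo = build_map(results, coll, overlap_threshold=0.3)
        hi = build_map(results, coll, overlap_threshold=0.7)
        top = build_map(results, coll, overlap_threshold=1.0)
        assert set(hi.graph.edges) <= set(lo.graph.edges)
        assert top.graph.number_of_edges() == 0  # no identical memberships

    def test_dual_map_nodes_are_union_of_single_maps(self):
        memberships = {"a": genes(0, 20), "b": genes(30, 50), "c": genes(60, 80)}
        coll = make_collection(memberships)
        res1 = [result("a"), result("b", p=0.5, q=0.9)]
        res2 = [result("b"), result("c", p=0.5, q=0.9)]
        single1 = build_map([res1], coll)
        single2 = build_map([res2], coll)
        dual = build_map([res1, res2], coll)
        assert set(dual.graph.nodes) == (
            set(single1.graph.nodes) | set(single2.graph.nodes)
        )
        node_a = [n for n in dual.nodes() if n.set_name == "a"][0]
        assert node_a.significant1 and not node_a.significant2
        node_b = [n for n in dual.nodes() if n.set_name == "b"][0]
        assert not node_b.significant1 and node_b.significant2

    def test_three_phenotypes_rejected(self):
        coll = make_collection({"a": genes(0, 20)})
        with pytest.raises(InputError, match="1 or 2"):
            build_map([[result("a")]] * 3, coll)

    def test_unresolved_set_names_rejected(self):
        coll = make_collection({"a": genes(0, 20)})
        with pytest.raises(InputError, match="ghost"):
            build_map([result("ghost")], coll)


class TestLayout:
    def _map_with(self, memberships):
        coll = make_collection(memberships)
        return build_map([result(n) for n in memberships], coll)

    def test_single_node_at_origin(self):
        g = self._map_with({"a": genes(0, 20)})
        assert layout(g) == {"a": (0.0, 0.0)}

    def test_seeded_determinism(self):
        memberships = {"a": genes(0, 10), "b": genes(2, 12), "c": genes(3, 13)}
        g = self._map_with(memberships)
        assert layout(g, seed=9) == layout(g, seed=9)

    def test_disconnected_cliques_are_separated(self):
        memberships = {
            "a1": genes(0, 10), "a2": genes(1, 11), "a3": genes(0, 11),
            "b1": genes(50, 60), "b2": genes(51, 61), "b3": genes(50, 61),
        }
        g = self._map_with(memberships)
        pos = layout(g, seed=1)
        ca = np.array([pos[n] for n in ("a1", "a2", "a3")])
        cb = np.array([pos[n] for n in ("b1", "b2", "b3")])
        centroid_dist = np.linalg.norm(ca.mean(0) - cb.mean(0))
        intra = max(
            np.linalg.norm(p - q)
            for pts in (ca, cb)
            for p in pts
            for q in pts
        )
        assert centroid_dist > intra


class TestSummarizeClusterTerms:
    def test_frequency_count(self):
        out = summarize_cluster_terms(
            ["integrin signaling", "integrin pathway"], set()
        )
        assert out == [("integrin", 2), ("pathway", 1), ("signaling", 1)]

    def test_empty_input(self):
        assert summarize_cluster_terms([], set()) == []

    def test_all_stopworded(self):
        assert summarize_cluster_terms(["of the and"], {"of", "the", "and"}) == []

    def test_case_folding(self):
        out = summarize_cluster_terms(["MAPK cascade", "mapk signaling"], set())
        assert out[0] == ("mapk", 2)


class TestExport:
    def _dual_map(self):
        memberships = {"a": genes(0, 20), "b": genes(2, 22), "c": genes(40, 60)}
        coll = make_collection(memberships)
        res1 = [result("a"), result("b")]
        res2 = [result("b"), result("c", es=-0.7)]
        return build_map([res1, res2], coll)

    def test_tables_round_trip(self, tmp_path):
        g = self._dual_map()
        pos = layout(g, seed=2)
        export_graph(g, str(tmp_path / "em"), "tables", pos)
        back = import_tables(str(tmp_path / "em"))
        assert set(back.graph.nodes) == set(g.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, g.graph.edges)
        )
        for n in g.graph.nodes:
            for key in ("set_size", "significant1", "significant2"):
                assert back.graph.nodes[n][key] == g.graph.nodes[n][key]
            for key in ("p1", "fdr1", "nes1", "p2", "fdr2", "nes2"):
                if key in g.graph.nodes[n]:
                    assert back.graph.nodes[n][key] == pytest.approx(
                        g.graph.nodes[n][key]
                    )
        for e in g.graph.edges:
            assert back.graph.edges[e]["overlap"] == pytest.approx(
                g.graph.edges[e]["overlap"]
            )

    def test_fixture_row_counts(self, tmp_path):
        g = self._dual_map()
        nodes_path, edges_path = export_graph(g, str(tmp_path / "em"), "tables")
        assert len(open(nodes_path).readlines()) == 1 + 3
        n_edges = g.graph.number_of_edges()
        assert len(open(edges_path).readlines()) == 1 + n_edges

    def test_empty_graph_exports_valid_tables(self, tmp_path):
        import networkx as nx
        g = EnrichmentMapGraph(graph=nx.Graph(), params={"n_phenotypes": 1})
        nodes_path, edges_path = export_graph(g, str(tmp_path / "empty"), "tables")
        back = import_tables(str(tmp_path / "empty"))
        assert back.graph.number_of_nodes() == 0

    def test_graphml_and_gml_written(self, tmp_path):
        import networkx as nx
        g = self._dual_map()
        (gml,) = export_graph(g, str(tmp_path / "em"), "gml")
        (graphml,) = export_graph(g, str(tmp_path / "em"), "graphml")
        assert nx.read_gml(gml).number_of_nodes() == 3
        assert nx.read_graphml(graphml).number_of_nodes() == 3

    def test_unsupported_format_rejected(self, tmp_path):
        g = self._dual_map()
        with pytest.raises(InputError, match="graphml"):
            export_graph(g, str(tmp_path / "em"), "dot")

    def test_render_writes_figure(self, tmp_path):
        g = self._dual_map()
        pos = layout(g, seed=2)
        out = tmp_path / "map.png"
        render(g, pos, str(out))
        assert out.stat().st_size > 0
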