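"""GO levels, visibility rules, branch pruning, and graph export."""

import networkx as nx
import pandas as pd
import pytest

from conftest import brute_force_ancestors
from ovaryseq.config import OntologyError, SimulationConfig
from ovaryseq.enrichment import compute_enrichment
from ovaryseq.gograph import (
    build_enrichment_graph,
    export_graph,
    read_graphml,
    read_sif,
    term_level,
    term_levels,
)
from ovaryseq.simulate import generate_go_dag


def _results(rows):
    """rows: (term_id, n_pre, n_mat, score); totals are irrelevant here."""
    return pd.DataFrame(
        [(t, t, "BP", np, 100, nm, 100, s) for t, np, nm, s in rows],
        columns=["term_id", "name", "namespace", "n_pre", "n_total_pre",
                 "n_mat", "n_total_mat", "score"],
    )


class TestTermLevel:
    def test_root_is_level_zero(self, chain_dag):
        assert term_level(chain_dag, "GO:0000001") == 0

    def test_direct_child_is_level_one(self, chain_dag):
        assert term_level(chain_dag, "GO:0000002") == 1

    def test_diamond_takes_shortest_path(self):
        # X -> P -> R (length 2) and X -> Q1 -> Q2 -> R (length 3)
        dag = nx.DiGraph(
            [("X", "P"), ("P", "R"), ("X", "Q1"), ("Q1", "Q2"), ("Q2", "R")]
        )
        assert term_level(dag, "X") == 2

    def test_unknown_term_rejected(self, chain_dag):
        with pytest.raises(OntologyError):
            term_level(chain_dag, "GO:404")

    @pytest.mark.parametrize("seed", range(5))
    def test_levels_match_brute_force_shortest_paths(self, seed):
        dag, _, _ = generate_go_dag(SimulationConfig(n_go_terms=80, seed=seed))
        levels = term_levels(dag)
        roots = {t for t in dag if dag.out_degree(t) == 0}
        for term in dag:
            expected = min(
                len(nx.shortest_path(dag, term, r)) - 1
                for r in roots
                if nx.has_path(dag, term, r)
            )
            assert levels[term] == expected


class TestVisibilityRules:
    def _dag(self):
        dag = nx.DiGraph([("c", "b"), ("b", "a")])
        for n in dag:
            dag.nodes[n].update(name=n, namespace="BP")
        return dag

    def test_149_genes_is_zero_sized(self):
        # strictly fewer than 150 carrying genes suppresses the node
        dag = self._dag()
        results = _results([("a", 100, 100, 0.0), ("b", 80, 69, 2.0), ("c", 75, 75, 2.0)])
        graph = build_enrichment_graph(dag, results, min_level=0, min_genes=150)
        assert graph.nodes["b"]["n_genes"] == 149
        assert graph.nodes["b"]["display_size"] == 0.0
        assert graph.nodes["c"]["display_size"] == 150.0

    def test_shallow_levels_are_zero_sized(self):
        dag = self._dag()
        results = _results([("a", 100, 100, 2.0), ("b", 100, 100, 2.0), ("c", 100, 100, 2.0)])
        graph = build_enrichment_graph(dag, results, min_level=2, min_genes=10)
        assert graph.nodes["a"]["display_size"] == 0.0  # level 0
        assert graph.nodes["b"]["display_size"] == 0.0  # level 1
        assert graph.nodes["c"]["display_size"] == 200.0  # level 2

    def test_rules_touch_display_only(self):
        dag = self._dag()
        results = _results([("a", 10, 10, 1.5), ("b", 5, 4, -2.0), ("c", 3, 3, 1.0)])
        graph = build_enrichment_graph(dag, results, min_level=2, min_genes=150)
        assert graph.nodes["b"]["score"] == -2.0
        assert graph.nodes["b"]["n_genes"] == 9
        assert graph.nodes["b"]["display_size"] == 0.0


class TestPruning:
    def test_all_flat_scores_empty_graph(self):
        dag = nx.DiGraph([("b", "a")])
        for n in dag:
            dag.nodes[n].update(name=n, namespace="BP")
        results = _results([("a", 5, 5, 0.0), ("b", 3, 3, 0.0)])
        graph = build_enrichment_graph(dag, results, sig_threshold=1.0)
        assert graph.number_of_nodes() == 0

    def test_significant_leaf_keeps_its_ancestors(self):
        dag = nx.DiGraph([("c", "b"), ("b", "a"), ("d", "a")])
        for n in dag:
            dag.nodes[n].update(name=n, namespace="BP")
        results = _results(
            [("a", 9, 9, 0.0), ("b", 5, 5, 0.1), ("c", 3, 1, 1.7), ("d", 4, 4, 0.0)]
        )
        graph = build_enrichment_graph(dag, results, sig_threshold=1.0)
        assert set(graph.nodes) == {"a", "b", "c"}  # d's branch is pruned
        assert set(graph.edges) == {("c", "b"), ("b", "a")}

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_matches_brute_force_oracle(self, seed):
        cfg = SimulationConfig(n_genes=200, n_go_terms=50, seed=seed)
        dag, ann, _ = generate_go_dag(cfg)
        genes = sorted(ann)
        pre, mat = set(genes[::2]), set(genes[1::2])
        results = compute_enrichment(dag, ann, pre, mat)
        graph = build_enrichment_graph(dag, results, sig_threshold=0.5)
        scored = dag.subgraph(results["term_id"])
        scores = results.set_index("term_id")["score"]
        expected = {
            t
            for t in scored
            if any(
                abs(scores[d]) >= 0.5
                for d in ({t} | nx.ancestors(scored, t))  # descendants-or-self
            )
        }
        assert set(graph.nodes) == expected

    def test_raising_threshold_never_adds_nodes(self):
        cfg = SimulationConfig(n_genes=200, n_go_terms=50, seed=1)
        dag, ann, _ = generate_go_dag(cfg)
        genes = sorted(ann)
        results = compute_enrichment(dag, ann, set(genes[::2]), set(genes[1::2]))
        previous = None
        for threshold in (0.0, 0.3, 0.6, 1.0, 2.0):
            nodes = set(build_enrichment_graph(dag, results, sig_threshold=threshold))
            if previous is not None:
                assert nodes <= previous
            previous = nodes

    def test_retained_edges_have_retained_endpoints(self):
        cfg = SimulationConfig(n_genes=200, n_go_terms=60, seed=2)
        dag, ann, _ = generate_go_dag(cfg)
        genes = sorted(ann)
        results = compute_enrichment(dag, ann, set(genes[::2]), set(genes[1::2]))
        graph = build_enrichment_graph(dag, results, sig_threshold=0.3)
        for child, parent in graph.edges:
            assert child in graph.nodes and parent in graph.nodes
            assert dag.has_edge(child, parent)


class TestExport:
    def _graph(self, seed=4):
        cfg = SimulationConfig(n_genes=200, n_go_terms=50, seed=seed)
        dag, ann, _ = generate_go_dag(cfg)
        genes = sorted(ann)
        results = compute_enrichment(dag, ann, set(genes[::2]), set(genes[1::2]))
        return build_enrichment_graph(dag, results, min_genes=20, sig_threshold=0.3)

    def test_empty_graph_exports_valid_files(self, tmp_path):
        paths = export_graph(nx.DiGraph(), tmp_path / "empty")
        assert read_graphml(paths["graphml"]).number_of_nodes() == 0
        assert paths["sif"].read_text() == ""

    def test_three_node_chain_sif_has_two_edges(self, tmp_path):
        graph = nx.DiGraph([("c", "b"), ("b", "a")])
        for n in graph:
            graph.nodes[n].update(
                name=n, namespace="BP", level=0, n_genes=1, score=0.0,
                display_size=0.0, visible=False,
            )
        paths = export_graph(graph, tmp_path / "chain")
        assert len(paths["sif"].read_text().splitlines()) == 2

    @pytest.mark.parametrize("reader", ["graphml", "sif"])
    def test_round_trip_preserves_attributes_exactly(self, tmp_path, reader):
        graph = self._graph()
        assert graph.number_of_nodes() > 0
        paths = export_graph(graph, tmp_path / "fig")
        if reader == "graphml":
            back = read_graphml(paths["graphml"])
        else:
            back = read_sif(paths["sif"], paths["nodes"])
        assert set(back.nodes) == set(graph.nodes)
        assert set(back.edges) == set(graph.edges)
        for term in graph.nodes:
            for key, value in graph.nodes[term].items():
                assert back.nodes[term][key] == value, (term, key)
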