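"""Ground-truth generator: determinism, bounds, planted structure."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ovaryseq.config import ConfigurationError, SimulationConfig
from ovaryseq.dedup import is_pcr_duplicate, similarity
from ovaryseq.quant import CLASS_MAT_UP, CLASS_NEITHER, CLASS_PRE_UP
from ovaryseq.simulate import (
    assign_classes,
    generate_counts,
    generate_gene_models,
    generate_go_dag,
    generate_qpcr_table,
    generate_reads_with_duplicates,
    max_duplicate_mismatches,
    simulate_all,
)


class TestGeneModels:
    def test_empty_request_rejected(self):
        with pytest.raises(ConfigurationError, match="n_genes"):
            generate_gene_models(SimulationConfig(n_genes=0))

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_genes=100, seed=1)
        assert generate_gene_models(cfg) == generate_gene_models(cfg)

    def test_lengths_within_range_and_ids_unique(self):
        cfg = SimulationConfig(n_genes=100, length_range=(500, 5000), seed=2)
        models = generate_gene_models(cfg)
        assert len({m.gene_id for m in models}) == 100
        assert all(500 <= m.length <= 5000 for m in models)

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError, match="length_range"):
            generate_gene_models(SimulationConfig(length_range=(100, 50)))


class TestCounts:
    def test_deterministic_for_fixed_seed(self, sim_config):
        models = generate_gene_models(sim_config)
        c1, t1 = generate_counts(models, sim_config)
        c2, t2 = generate_counts(models, sim_config)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_fractions_match_config(self):
        cfg = SimulationConfig(n_genes=1000, frac_pre_up=0.1, frac_mat_up=0.2, seed=3)
        truth = assign_classes(cfg)
        counts = truth["true_class"].value_counts()
        assert counts[CLASS_PRE_UP] == 100
        assert counts[CLASS_MAT_UP] == 200
        assert counts[CLASS_NEITHER] == 700

    def test_degenerate_config_all_unchanged(self):
        cfg = SimulationConfig(n_genes=50, frac_pre_up=0.0, frac_mat_up=0.0, seed=0)
        models = generate_gene_models(cfg)
        _, truth = generate_counts(models, cfg)
        assert (truth["true_class"] == CLASS_NEITHER).all()

    def test_poisson_limit_recovers_planted_fold(self):
        # near-zero dispersion makes the gamma-Poisson mixture Poisson; the
        # empirical mean ratio of planted genes approaches true_fold
        cfg = SimulationConfig(
            n_genes=1000,
            length_range=(1000, 1000),
            library_size=1_000_000,
            dispersion=1e-8,
            abundance_sigma=0.0,
            true_fold=2.0,
            seed=5,
        )
        models = generate_gene_models(cfg)
        counts, truth = generate_counts(models, cfg)
        merged = counts.merge(truth, on="gene_id")
        pre_up = merged[merged["true_class"] == CLASS_PRE_UP]
        means = pre_up.groupby("condition")["count"].mean()
        ratio = means["premature"] / means["mature"]
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_nonpositive_dispersion_rejected(self, sim_config):
        models = generate_gene_models(sim_config)
        bad = dataclasses.replace(sim_config, dispersion=0.0)
        with pytest.raises(ConfigurationError, match="dispersion"):
            generate_counts(models, bad)


class TestGoDag:
    def test_acyclic_and_rooted_per_namespace(self, sim_config):
        dag, _, _ = generate_go_dag(sim_config)
        assert nx.is_directed_acyclic_graph(dag)
        roots = [t for t in dag if dag.out_degree(t) == 0]
        assert len(roots) == 3
        for term in dag:
            ns = dag.nodes[term]["namespace"]
            for parent in dag.successors(term):
                assert dag.nodes[parent]["namespace"] == ns

    def test_every_nonroot_has_a_parent(self, sim_config):
        dag, _, _ = generate_go_dag(sim_config)
        roots = {t for t in dag if dag.out_degree(t) == 0}
        for term in dag:
            if term not in roots:
                assert dag.out_degree(term) >= 1

    def test_deterministic(self, sim_config):
        d1, a1, t1 = generate_go_dag(sim_config)
        d2, a2, t2 = generate_go_dag(sim_config)
        assert set(d1.edges) == set(d2.edges)
        assert a1 == a2 and t1 == t2

    def test_planted_terms_are_leaves(self, sim_config):
        dag, _, truth = generate_go_dag(sim_config)
        for term, _ in truth:
            assert dag.in_degree(term) == 0  # no children feed into them


class TestReads:
    def test_zero_dup_rate_empty_truth(self, sim_config):
        cfg = dataclasses.replace(sim_config, dup_rate=0.0)
        _, truth, _ = generate_reads_with_duplicates(cfg)
        assert truth == {}

    def test_invalid_dup_rate_rejected(self, sim_config):
        with pytest.raises(ConfigurationError, match="dup_rate"):
            generate_reads_with_duplicates(dataclasses.replace(sim_config, dup_rate=1.5))

    def test_planted_duplicates_satisfy_predicate(self, sim_config):
        reads, truth, _ = generate_reads_with_duplicates(sim_config)
        by_id = {r.read_id: r for r in reads}
        assert truth
        for dup, orig in truth.items():
            assert is_pcr_duplicate(by_id[dup], by_id[orig])

    def test_decoys_fail_predicate_but_share_prefix(self, sim_config):
        reads, _, decoys = generate_reads_with_duplicates(sim_config)
        by_id = {r.read_id: r for r in reads}
        assert decoys
        for decoy in decoys:
            orig = by_id[decoy.replace("_decoy", "")]
            assert by_id[decoy].sequence[:10] == orig.sequence[:10]
            assert not is_pcr_duplicate(by_id[decoy], orig)
            assert similarity(by_id[decoy], orig) <= 0.90

    def test_duplicate_of_100mer_has_at_most_9_mismatches(self):
        # 9/100 mismatches -> 91% identity; 10 would hit the boundary
        assert max_duplicate_mismatches(100, 0.90) == 9
        cfg = SimulationConfig(read_length=100, dup_rate=1.0, n_reads=40, seed=11)
        reads, truth, _ = generate_reads_with_duplicates(cfg)
        by_id = {r.read_id: r for r in reads}
        for dup, orig in truth.items():
            mm = sum(a != b for a, b in zip(by_id[dup].sequence, by_id[orig].sequence))
            assert mm <= 9

    def test_decoy_of_100mer_has_at_least_10_mismatches(self):
        cfg = SimulationConfig(read_length=100, decoy_rate=1.0, n_reads=40, seed=12)
        reads, _, decoys = generate_reads_with_duplicates(cfg)
        by_id = {r.read_id: r for r in reads}
        assert decoys
        for decoy in decoys:
            orig = by_id[decoy.replace("_decoy", "")]
            mm = sum(a != b for a, b in zip(by_id[decoy].sequence, orig.sequence))
            assert mm >= 10
            assert all(
                a == b for a, b in zip(by_id[decoy].sequence[:10], orig.sequence[:10])
            )


class TestQpcrTable:
    def test_folds_encode_planted_classes(self, sim_config):
        table = generate_qpcr_table(sim_config)
        truth = assign_classes(sim_config).set_index("gene_id")["true_class"]
        for row in table.itertuples(index=False):
            delta = row.ct_mature - row.ct_premature
            cls = truth[row.gene_id]
            if cls == CLASS_PRE_UP:
                assert 2.0 ** delta == pytest.approx(sim_config.true_fold)
            elif cls == CLASS_MAT_UP:
                assert 2.0 ** delta == pytest.approx(1 / sim_config.true_fold)
            else:
                assert delta == pytest.approx(0.0)


class TestFileBundle:
    def test_byte_identical_across_runs(self, tmp_path, sim_config):
        paths1 = simulate_all(sim_config, tmp_path / "a")
        paths2 = simulate_all(sim_config, tmp_path / "b")
        for name in paths1:
            assert paths1[name].read_bytes() == paths2[name].read_bytes(), name
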