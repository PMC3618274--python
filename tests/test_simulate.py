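"""Synthetic dataset generator: trees, sequences, indels, IO, round trips."""

import itertools
import json

import numpy as np
import pytest

from motudelim.distances import compute_distance_matrix, k2p_distance
from motudelim.seqdata import check_ultrametric, find_diagnostic_columns
from motudelim.simulate import (
    SimConfig,
    evolve_sequences,
    inject_indels,
    simulate_dataset,
    simulate_tree,
    write_dataset,
)


class TestSimulateTree:
    def test_single_species_is_pure_coalescent(self):
        cfg = SimConfig(K=1, n_k=(8,), seed=2)
        truth = simulate_tree(cfg)
        assert len(truth.tree.leaf_nodes()) == 8
        assert truth.species == ["sp1"]
        check_ultrametric(truth.tree, tolerance=1e-9)

    def test_fixed_seed_reproduces_newick(self):
        t1 = simulate_tree(SimConfig(seed=42)).tree.as_string(schema="newick")
        t2 = simulate_tree(SimConfig(seed=42)).tree.as_string(schema="newick")
        assert t1 == t2

    def test_partition_matches_sample_sizes(self):
        cfg = SimConfig(seed=0)
        truth = simulate_tree(cfg)
        sizes = sorted(
            sum(1 for g in truth.partition.values() if g == sp)
            for sp in truth.species)
        assert sizes == sorted(cfg.n_k)

    def test_tree_is_binary_and_ultrametric(self):
        truth = simulate_tree(SimConfig(seed=9))
        check_ultrametric(truth.tree, tolerance=1e-9)
        for nd in truth.tree.preorder_internal_node_iter():
            assert len(nd.child_nodes()) == 2

    def test_between_vs_within_separation_at_high_depth_ratio(self):
        """With species depth 20x the coalescent scale, mean between-species
        patristic distance dwarfs the within-species distance."""
        ok = 0
        for seed in range(10):
            cfg = SimConfig(K=7, n_k=(4,) * 7, species_depth=0.1,
                            pop_scale=0.005, seed=seed)
            truth = simulate_tree(cfg)
            pdm = truth.tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in truth.tree.taxon_namespace}
            within, between = [], []
            for a, b in itertools.combinations(sorted(taxa), 2):
                d = pdm.patristic_distance(taxa[a], taxa[b])
                same = truth.partition[a] == truth.partition[b]
                (within if same else between).append(d)
            if np.mean(between) / np.mean(within) >= 10:
                ok += 1
        assert ok >= 9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(K=0, n_k=())
        with pytest.raises(ValueError):
            SimConfig(K=2, n_k=(3,))
        with pytest.raises(ValueError):
            SimConfig(K=1, n_k=(0,))


class TestEvolveSequences:
    def test_zero_branch_child_identical(self):
        cfg = SimConfig(K=1, n_k=(2,), seed=5, seq_length=200)
        truth = simulate_tree(cfg)
        for nd in truth.tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = 0.0
        locus = evolve_sequences(truth.tree, cfg)
        assert locus.rows[0] == locus.rows[1]

    def test_k2p_estimate_recovers_path_length(self):
        """Two tips at path distance 0.1 with a long sequence: estimated
        K2P distance ~ 0.1 (law of large numbers)."""
        import dendropy
        taxa = dendropy.TaxonNamespace(["x", "y"])
        a = dendropy.Node(taxon=taxa[0])
        b = dendropy.Node(taxon=taxa[1])
        root = dendropy.Node()
        root.add_child(a)
        root.add_child(b)
        a.edge.length = b.edge.length = 0.05
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        cfg = SimConfig(K=1, n_k=(1,), seq_length=100_000, seed=3)
        locus = evolve_sequences(tree, cfg)
        d = k2p_distance(locus.rows[0], locus.rows[1])
        assert d == pytest.approx(0.1, abs=0.005)

    def test_large_kappa_suppresses_transversions(self):
        import dendropy
        taxa = dendropy.TaxonNamespace(["x", "y"])
        a, b = dendropy.Node(taxon=taxa[0]), dendropy.Node(taxon=taxa[1])
        root = dendropy.Node()
        root.add_child(a)
        root.add_child(b)
        a.edge.length = b.edge.length = 0.05
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        cfg = SimConfig(K=1, n_k=(1,), seq_length=20_000, seed=3, kappa=5000.0)
        locus = evolve_sequences(tree, cfg)
        purines, pyrimidines = set("AG"), set("CT")
        tv = sum(1 for x, y in zip(*locus.rows)
                 if x != y and not (
                     {x, y} <= purines or {x, y} <= pyrimidines))
        ts = sum(1 for x, y in zip(*locus.rows)
                 if x != y) - tv
        assert ts > 100
        assert tv <= 2


class TestInjectIndels:
    def test_roundtrip_with_diagnostic_column_finder(self):
        cfg = SimConfig(K=3, n_k=(3, 3, 3), seed=8, seq_length=300,
                        indel_blocks=1, indel_length=3)
        truth, locus = simulate_dataset(cfg)
        gm = truth.group_map()
        for sp in truth.species:
            found = [c for c, _, _ in find_diagnostic_columns(locus, gm, sp)]
            assert set(truth.diagnostic_columns[sp]) <= set(found)

    def test_zero_blocks_leaves_alignment_unchanged(self):
        cfg = SimConfig(K=2, n_k=(2, 2), seed=1, seq_length=100)
        truth = simulate_tree(cfg)
        locus = evolve_sequences(truth.tree, cfg)
        out, cols = inject_indels(locus, truth.group_map(), cfg)
        assert out.rows == locus.rows
        assert cols == {}

    def test_blocks_disjoint_across_species(self):
        cfg = SimConfig(K=4, n_k=(2, 2, 2, 2), seed=3, seq_length=400,
                        indel_blocks=2, indel_length=4)
        truth, locus = simulate_dataset(cfg)
        all_cols = [c for cols in truth.diagnostic_columns.values()
                    for c in cols]
        assert len(all_cols) == len(set(all_cols)) == 4 * 2 * 4

    def test_blocks_not_fitting_rejected(self):
        cfg = SimConfig(K=2, n_k=(2, 2), seed=1, seq_length=10,
                        indel_blocks=3, indel_length=3)
        truth = simulate_tree(cfg)
        locus = evolve_sequences(truth.tree, cfg)
        with pytest.raises(ValueError, match="fit"):
            inject_indels(locus, truth.group_map(), cfg)


class TestWriteDataset:
    def test_files_and_manifest(self, tmp_path):
        cfg = SimConfig(K=2, n_k=(2, 3), seed=6, seq_length=80)
        truth, locus = simulate_dataset(cfg)
        manifest = write_dataset(truth, locus, tmp_path / "d")
        assert set(manifest) == {"fasta", "tree", "partition", "config"}
        assert (tmp_path / "d" / "manifest.json").exists()
        stored = json.loads((tmp_path / "d" / "sim_config.json").read_text())
        assert stored["seed"] == 6

    def test_same_seed_identical_checksums(self, tmp_path):
        cfg = SimConfig(K=2, n_k=(2, 3), seed=6, seq_length=80)
        m1 = write_dataset(*simulate_dataset(cfg), tmp_path / "a")
        truth, locus = simulate_dataset(cfg)
        m2 = write_dataset(truth, locus, tmp_path / "b")
        assert {k: v["sha256"] for k, v in m1.items()} == \
               {k: v["sha256"] for k, v in m2.items()}

    def test_truth_partition_has_k_labels(self, tmp_path):
        cfg = SimConfig(seed=0)
        truth, locus = simulate_dataset(cfg)
        write_dataset(truth, locus, tmp_path / "x")
        lines = (tmp_path / "x" / "truth_partition.tsv").read_text().splitlines()
        labels = {l.split("\t")[1] for l in lines}
        assert len(labels) == 7
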