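"""Monophyly, GSI, Holm correction, P_AB, P(RD) and SDP summaries."""

import itertools
import math

import numpy as np
import pytest

from motudelim.seqdata import GroupMap
from motudelim.tree_delim import (
    gsi,
    gsi_test,
    is_monophyletic,
    patristic_matrix,
    rodrigo_prd,
    rosenberg_pab,
    rosenberg_pab_enumeration,
    sdp_summary,
    sequential_bonferroni,
    simulate_coalescent_tree,
)
from conftest import tree_from_newick


class TestMonophyly:
    def test_cherry_is_monophyletic(self, balanced_tree):
        assert is_monophyletic(balanced_tree, {"a", "b"})

    def test_split_pair_is_not(self, balanced_tree):
        assert not is_monophyletic(balanced_tree, {"a", "c"})

    def test_agrees_with_descendant_enumeration_on_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree = simulate_coalescent_tree(8, rng)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            group = set(rng.choice(tips, size=3, replace=False))
            # oracle: some node's exact descendant set equals the group
            oracle = any(
                {l.taxon.label for l in nd.leaf_iter()} == group
                for nd in tree.preorder_node_iter())
            assert is_monophyletic(tree, group) == oracle


class TestGsi:
    def test_monophyletic_group_scores_one(self, balanced_tree):
        assert gsi(balanced_tree, {"a", "b"}) == pytest.approx(1.0)

    def test_range_and_monophyly_iff_one_on_all_6_tip_shapes(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            tree = simulate_coalescent_tree(6, rng)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            for size in (2, 3):
                for group in itertools.combinations(tips, size):
                    value = gsi(tree, set(group))
                    assert -1e-9 <= value <= 1 + 1e-9
                    mono = is_monophyletic(tree, set(group))
                    assert (abs(value - 1) < 1e-9) == mono

    def test_caterpillar_matches_direct_formula(self):
        # caterpillar: tips t1..t8, group = the two ends {t1, t8}
        newick = "(((((((t1:1,t2:1):1,t3:2):1,t4:3):1,t5:4):1,t6:5):1,t7:6):1,t8:7);"
        tree = tree_from_newick(newick)
        # U = every internal node (7 of them, binary): GS = 2/7 = GS_min -> 0
        assert gsi(tree, {"t1", "t8"}) == pytest.approx(0.0)
        # group {t1, t2}: U = {cherry}: GS = 2/1; GS_min = 2/7; GS_max = 2/1
        assert gsi(tree, {"t1", "t2"}) == pytest.approx(1.0)
        # group {t1, t3}: U = cherry's parent + cherry = 2 nodes: GS = 2/2
        g = (2 / 2 - 2 / 7) / (2 / 1 - 2 / 7)
        assert gsi(tree, {"t1", "t3"}) == pytest.approx(g)

    def test_monophyletic_group_has_small_p(self):
        rng = np.random.default_rng(1)
        tree = simulate_coalescent_tree(20, rng)
        # pick a real clade of size 5 if one exists, else make do with 4..6
        clade = None
        for nd in tree.preorder_internal_node_iter():
            tips = {l.taxon.label for l in nd.leaf_iter()}
            if 4 <= len(tips) <= 6 and nd.parent_node is not None:
                clade = tips
                break
        assert clade is not None
        res = gsi_test(tree, clade, n_perm=999, seed=5)
        assert res.gsi == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_permutation_p_valid_under_random_labels(self):
        """Under random group labels the permutation p-value is valid
        (super-uniform): the test rejects at most at its nominal rate.
        Exact uniformity is unattainable because the index is discrete on a
        small tree (ties inflate p), so the check is one-sided validity
        plus non-degeneracy of the distribution."""
        rng = np.random.default_rng(17)
        tree = simulate_coalescent_tree(10, rng)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        pvals = []
        for k in range(300):
            group = set(rng.choice(tips, size=4, replace=False))
            pvals.append(gsi_test(tree, group, n_perm=99, seed=int(k)).p_value)
        pvals = np.asarray(pvals)
        assert (pvals <= 0.05).mean() <= 0.08  # size not exceeded
        assert (pvals <= 0.25).mean() <= 0.30
        assert pvals.min() < 0.2 and pvals.max() > 0.9  # spread, not point mass


class TestSequentialBonferroni:
    def test_holm_hand_example(self):
        # m=2: 0.001 <= 0.05/2 -> sig; then 0.04 <= 0.05/1 -> sig
        assert sequential_bonferroni([0.001, 0.04], alpha=0.05) == [True, True]

    def test_stops_at_first_failure(self):
        # sorted: 0.001 <= 0.0167, 0.03 > 0.025 -> stop; 0.04 not tested
        flags = sequential_bonferroni([0.04, 0.001, 0.03], alpha=0.05)
        assert flags == [False, True, False]

    def test_all_ones_none_significant(self):
        assert sequential_bonferroni([1.0, 1.0, 1.0]) == [False] * 3

    def test_single_p(self):
        assert sequential_bonferroni([0.04], alpha=0.05) == [True]

    def test_matches_statsmodels_holm(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0, 0.2, size=6)
            ours = sequential_bonferroni(list(p), alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            assert ours == list(ref)


class TestRosenbergPab:
    def test_two_singletons_trivially_monophyletic(self):
        assert rosenberg_pab(1, 1).p_ab == 1.0

    def test_two_two_is_one_ninth(self):
        assert rosenberg_pab(2, 2).p_ab == pytest.approx(1 / 9)

    @pytest.mark.parametrize("a,b", [(a, b) for a in range(1, 8)
                                     for b in range(1, 8) if a + b <= 8])
    def test_closed_form_matches_enumeration(self, a, b):
        cf = rosenberg_pab(a, b).p_ab
        en = rosenberg_pab_enumeration(a, b).p_ab
        assert cf == pytest.approx(en, abs=1e-12)

    def test_probability_decreases_with_size(self):
        vals = [rosenberg_pab(k, k).p_ab for k in range(1, 7)]
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestRodrigoPrd:
    def test_zero_stem_least_distinct(self):
        tree = tree_from_newick("((a:1,b:1):0.0,(c:1,d:1):1);")
        node = tree.mrca(taxon_labels=["a", "b"])
        res = rodrigo_prd(tree, node, n_sim=50, seed=1)
        assert math.isinf(res.r_obs)
        assert res.p_value == 1.0

    def test_long_stem_small_ratio_small_p(self):
        tree = tree_from_newick("((a:0.01,b:0.01):5.0,(c:1,d:1):4.01);")
        node = tree.mrca(taxon_labels=["a", "b"])
        res = rodrigo_prd(tree, node, n_sim=400, seed=2)
        assert res.r_obs == pytest.approx(0.002)
        assert res.p_value < 0.05

    def test_root_rejected(self, balanced_tree):
        with pytest.raises(ValueError):
            rodrigo_prd(balanced_tree, balanced_tree.seed_node, n_sim=10, seed=0)

    def test_null_calibration_roughly_uniform(self):
        """Clades sampled from single-population coalescents get p-values
        spread over (0,1), not piled near 0."""
        rng = np.random.default_rng(23)
        pvals = []
        for k in range(40):
            tree = simulate_coalescent_tree(10, rng)
            cands = [nd for nd in tree.preorder_internal_node_iter()
                     if nd.parent_node is not None]
            node = cands[int(rng.integers(len(cands)))]
            pvals.append(rodrigo_prd(tree, node, n_sim=60,
                                     seed=int(k)).p_value)
        assert 0.25 < np.mean(pvals) < 0.75
        assert sum(p < 0.05 for p in pvals) <= 6


class TestSdpSummary:
    def make(self):
        newick = "(((a1:0.1,a2:0.1):2.0,(b1:0.1,b2:0.1):2.0):1.0,c1:3.1);"
        tree = tree_from_newick(newick)
        groups = GroupMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                           "c1": "C"})
        return tree, groups

    def test_separated_clades_fully_identifiable(self):
        tree, groups = self.make()
        s = sdp_summary(tree, groups, "A")
        assert s.p_id_strict == 1.0
        assert s.intra == pytest.approx(0.2)
        assert s.closest_group == "B"

    def test_closest_group_minimizes_mean_patristic(self):
        tree, groups = self.make()
        labels, mat = patristic_matrix(tree)
        idx = {l: k for k, l in enumerate(labels)}
        means = {}
        for g in ("B", "C"):
            gids = sorted(groups.members(g))
            means[g] = np.mean([mat[idx[i], idx[j]]
                                for i in ("a1", "a2") for j in gids])
        s = sdp_summary(tree, groups, "A")
        assert s.closest_group == min(means, key=means.get)
        assert s.inter == pytest.approx(means[s.closest_group])

    def test_singleton_intra_not_applicable(self):
        tree, groups = self.make()
        s = sdp_summary(tree, groups, "C")
        assert s.intra is None and s.ratio is None

    def test_wilson_ci_brackets_estimate(self):
        tree, groups = self.make()
        s = sdp_summary(tree, groups, "B")
        lo, hi = s.p_id_ci
        assert lo <= s.p_id_strict <= hi
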