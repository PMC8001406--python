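from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix, TreeNode

from bandpop.distances import jaccard_distance, squared_band_distance, standardized_euclidean
from bandpop.io import BandMatrix, TraitTable
from bandpop.simulate import worked_fixture
from bandpop.trees import bipartitions, bootstrap_support, nj_tree, upgma_clusters, upgma_tree
from tests.conftest import random_band_matrix


class TestJaccard:
    def test_identical_and_disjoint(self):
        bm = BandMatrix(["a", "b", "c"], ["P1_1", "P1_2", "P1_3"],
                        np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], float))
        d = jaccard_distance(bm)
        assert d["a", "b"] == 0.0
        assert d["a", "c"] == 1.0

    def test_hand_count(self):
        bm = BandMatrix(["a", "b"], ["P1_1", "P1_2", "P1_3"],
                        np.array([[1, 1, 0], [1, 0, 1]], float))
        assert jaccard_distance(bm)["a", "b"] == pytest.approx(2 / 3)

    def test_fixture_pair(self, fixture_panel):
        bm, _, _ = fixture_panel
        assert jaccard_distance(bm)["g1", "g2"] == 0.5

    def test_empty_pair_warns(self):
        bm = BandMatrix(["a", "b"], ["P1_1"], np.array([[0], [0]], float))
        with pytest.warns(UserWarning, match="no informative band"):
            d = jaccard_distance(bm)
        assert d["a", "b"] == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        bm = random_band_matrix(rng, int(rng.integers(3, 15)), n_bands=8)
        d = jaccard_distance(bm).data
        n = d.shape[0]
        for i, j, k in combinations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestStandardizedEuclidean:
    def _tt(self, values, traits=("T1",)):
        import pandas as pd
        rows = [(f"g{i}", t, 1, v)
                for i, vals in enumerate(values)
                for t, v in zip(traits, np.atleast_1d(vals))]
        return TraitTable(pd.DataFrame(rows, columns=["genotype", "trait",
                                                      "replicate", "value"]))

    def test_identical_profiles(self):
        tt = self._tt([(1.0, 2.0), (1.0, 2.0), (3.0, 5.0)], ("T1", "T2"))
        assert standardized_euclidean(tt)["g0", "g1"] == 0.0

    def test_two_point_closed_form(self):
        # one trait, values {0, 1}: z = -/+ 1/sqrt(2), d = sqrt(2)
        tt = self._tt([0.0, 1.0])
        assert standardized_euclidean(tt)["g0", "g1"] == pytest.approx(np.sqrt(2))

    def test_scale_invariance(self):
        base = [(1.0, 5.0), (2.0, 9.0), (4.0, 7.0)]
        tt1 = self._tt(base, ("T1", "T2"))
        tt2 = self._tt([(a, 10 * b) for a, b in base], ("T1", "T2"))
        np.testing.assert_allclose(
            standardized_euclidean(tt1).data, standardized_euclidean(tt2).data)

    def test_zero_sd_trait_named(self):
        tt = self._tt([(1.0, 3.0), (2.0, 3.0), (4.0, 3.0)], ("T1", "T2"))
        with pytest.raises(ValueError, match="T2"):
            standardized_euclidean(tt)


def additive_matrix_from_tree(tree: TreeNode) -> DistanceMatrix:
    tt = tree.tip_tip_distances()
    return DistanceMatrix(tt.data, list(tt.ids))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        gen = TreeNode.read(["((A:1,B:2):1,(C:3,D:1):1);"])
        dm = additive_matrix_from_tree(gen)
        tree = nj_tree(dm)
        recovered = tree.tip_tip_distances()
        np.testing.assert_allclose(
            recovered.filter(dm.ids).data, dm.data, atol=1e-9)
        assert bipartitions(tree) == bipartitions(gen)

    def test_equidistant_three_taxa(self):
        # symmetric star: every tip-to-tip path keeps length 2
        dm = DistanceMatrix(2 * (np.ones((3, 3)) - np.eye(3)), ["A", "B", "C"])
        tree = nj_tree(dm)
        rec = tree.tip_tip_distances().filter(["A", "B", "C"])
        np.testing.assert_allclose(rec.data, dm.data, atol=1e-9)

    def test_deterministic_under_ties(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("ABCD"))
        s1 = str(nj_tree(dm))
        s2 = str(nj_tree(dm))
        assert s1 == s2

    def test_negative_branches_truncated(self):
        d = np.array([
            [0, 1, 9, 9],
            [1, 0, 9, 9.2],
            [9, 9, 0, 0.1],
            [9, 9.2, 0.1, 0]], float)
        with pytest.warns(UserWarning, match="negative"):
            tree = nj_tree(DistanceMatrix(d, list("ABCD")))
        assert all((t.length or 0) >= 0 for t in tree.traverse())

    def test_matches_minimum_evolution_on_five_taxa(self):
        """NJ equals the brute-force minimum total-branch-length search
        over all 5-taxon topologies on an additive matrix."""
        gen = TreeNode.read(["(((A:1.0,B:0.5):0.7,C:1.2):0.4,(D:0.9,E:1.1):0.6);"])
        dm = additive_matrix_from_tree(gen)
        nj = nj_tree(dm)
        assert bipartitions(nj) == bipartitions(gen)
        # oracle: every unrooted 5-taxon topology, least-squares branch fit
        best_len, best_parts = np.inf, None
        labels = list(dm.ids)
        for newick in _all_unrooted_five(labels):
            tree = TreeNode.read([newick])
            length, ok = _ls_branch_fit(tree, dm)
            if ok and length < best_len - 1e-9:
                best_len, best_parts = length, bipartitions(tree)
        assert best_parts == bipartitions(nj)

    def test_skbio_cross_check(self, small_panel):
        from skbio.tree import nj as skbio_nj

        bm, _, _ = small_panel
        dm = jaccard_distance(bm)
        ours = nj_tree(dm)
        theirs = skbio_nj(dm)
        ours_d = ours.tip_tip_distances()
        theirs_d = theirs.tip_tip_distances().filter(ours_d.ids)
        # same additive approximation up to negative-branch truncation
        assert np.corrcoef(ours_d.data.ravel(), theirs_d.data.ravel())[0, 1] > 0.99


def _all_unrooted_five(labels):
    """The 15 unrooted binary topologies on 5 taxa as Newick strings."""
    seen = set()
    out = []
    for perm in permutations(labels):
        a, b, c, d, e = perm
        for nwk, key in [
            (f"(({a},{b}),({c},{d}),{e});",
             frozenset([frozenset([a, b]), frozenset([c, d])])),
        ]:
            if key not in seen:
                seen.add(key)
                out.append(nwk)
    return out


def _ls_branch_fit(tree, dm):
    """Least-squares branch lengths for a fixed topology; returns (total
    length, feasible) with negative estimates deemed infeasible."""
    tips = list(tree.tips())
    edges = [n for n in tree.traverse(include_self=False)]
    paths = np.zeros((len(tips) * (len(tips) - 1) // 2, len(edges)))
    target = []
    row = 0
    index = {id(e): k for k, e in enumerate(edges)}
    for i, j in combinations(range(len(tips)), 2):
        anc = tree.lowest_common_ancestor([tips[i], tips[j]])
        for tip in (tips[i], tips[j]):
            node = tip
            while node is not anc:
                paths[row, index[id(node)]] = 1
                node = node.parent
        target.append(dm[tips[i].name, tips[j].name])
        row += 1
    coef, *_ = np.linalg.lstsq(paths, np.asarray(target), rcond=None)
    return float(coef.sum()), bool((coef > -1e-9).all())


class TestUpgma:
    def test_ultrametric_recovery(self):
        # ultrametric: d(A,B)=2, d(A,C)=d(B,C)=6
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        tree = upgma_tree(DistanceMatrix(d, list("ABC")))
        rec = tree.tip_tip_distances()
        np.testing.assert_allclose(rec.filter(list("ABC")).data, d, atol=1e-9)

    def test_two_items_join_at_half_distance(self):
        dm = DistanceMatrix(np.array([[0, 3], [3, 0]], float), ["A", "B"])
        tree = upgma_tree(dm)
        assert {t.length for t in tree.tips()} == {1.5}

    def test_cut_produces_requested_groups(self, fixture_panel):
        bm, _, tt = fixture_panel
        dm = standardized_euclidean(tt)
        flat = upgma_clusters(dm, height=1.0)
        assert set(flat) == set(dm.ids)
        assert len(set(flat.values())) >= 2


class TestBootstrap:
    def test_separated_clusters_get_full_support(self):
        from bandpop.simulate import PanelSpec, simulate_panel

        spec = PanelSpec(group_sizes=(6, 6), group_names=("A", "B"),
                         group_clusters=(0, 1), n_clusters=2,
                         primer_classes={f"P{i}": "All" for i in range(1, 11)},
                         divergence_f=0.7, alpha=0.01)
        bm, popmap, _ = simulate_panel(spec, seed=3)
        tree = bootstrap_support(bm, nj_tree, n_reps=200, seed=4)
        split = frozenset(g for g in bm.genotype_ids if popmap[g] == "B")
        tips = sorted(t.name for t in tree.tips())
        anchor = tips[0]
        if anchor in split:
            split = frozenset(set(tips) - split)
        supports = {}
        for node in tree.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            if anchor in side:
                side = set(tips) - side
            supports[frozenset(side)] = node.support
        assert supports.get(split, 0) >= 99.0

    def test_single_rep_supports_binary(self, small_panel):
        bm, _, _ = small_panel
        tree = bootstrap_support(bm, nj_tree, n_reps=1, seed=0)
        vals = {n.support for n in tree.non_tips(include_self=False)}
        assert vals <= {0.0, 100.0}

    def test_seeded_determinism(self, small_panel):
        bm, _, _ = small_panel
        t1 = bootstrap_support(bm, nj_tree, n_reps=25, seed=7)
        t2 = bootstrap_support(bm, nj_tree, n_reps=25, seed=7)
        assert str(t1) == str(t2)
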