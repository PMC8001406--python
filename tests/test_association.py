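import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix

from bandpop.association import (anova_tukey, compact_letters, fold_range,
                                 kruskal_wallis, mantel, smra,
                                 trait_correlations)
from bandpop.io import BandMatrix, TraitTable
from bandpop.simulate import PanelSpec, TraitSpec, simulate_panel, simulate_traits


def _tt(values_by_trait):
    rows = [(f"g{i}", t, 1, v)
            for t, vals in values_by_trait.items() for i, v in enumerate(vals)]
    return TraitTable(pd.DataFrame(rows, columns=["genotype", "trait",
                                                  "replicate", "value"]))


class TestMantel:
    def _random_dm(self, rng, n=12):
        pts = rng.normal(size=(n, 2))
        from scipy.spatial.distance import pdist, squareform
        return DistanceMatrix(squareform(pdist(pts)), [f"g{i}" for i in range(n)])

    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        d = self._random_dm(rng)
        res = mantel(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        d = self._random_dm(rng)
        d2 = DistanceMatrix(3.0 * d.data + 0.5 * (1 - np.eye(d.shape[0])),
                            list(d.ids))
        assert mantel(d, d2, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        d1, d2 = self._random_dm(rng), self._random_dm(rng)
        r_base = mantel(d1, d2, n_perm=9, seed=0).r
        new = {i: f"x{i}" for i in d1.ids}
        d1r = DistanceMatrix(d1.data, [new[i] for i in d1.ids])
        d2r = DistanceMatrix(d2.data, [new[i] for i in d2.ids])
        assert mantel(d1r, d2r, n_perm=9, seed=0).r == pytest.approx(r_base)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        d1 = self._random_dm(rng)
        d2 = DistanceMatrix(d1.data, [f"y{i}" for i in range(d1.shape[0])])
        with pytest.raises(ValueError, match="labels"):
            mantel(d1, d2)

    def test_null_p_uniform(self):
        """Under independence the permutation p-value is approximately
        Uniform(0, 1] (KS check over seeded repetitions)."""
        rng = np.random.default_rng(4)
        ps = []
        for s in range(200):
            d1, d2 = self._random_dm(rng, 10), self._random_dm(rng, 10)
            ps.append(mantel(d1, d2, n_perm=99, seed=s).p_value)
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01


class TestTraitCorrelations:
    def test_r_squared_identity_and_perfect_line(self):
        x = np.linspace(1, 10, 12)
        tt = _tt({"A": x, "B": 2 * x + 1, "C": x + np.sin(x)})
        table = trait_correlations(tt)
        ab = table[(table.trait_x == "A") & (table.trait_y == "B")].iloc[0]
        assert ab.r == pytest.approx(1.0)
        assert ab.slope == pytest.approx(2.0)
        assert ab.intercept == pytest.approx(1.0)
        for _, row in table.iterrows():
            assert row.r2 == pytest.approx(row.r ** 2)
            assert row.r_ci_low <= row.r <= row.r_ci_high

    def test_constant_trait_rejected(self):
        tt = _tt({"A": [1, 2, 3], "B": [5, 5, 5]})
        with pytest.raises(ValueError):
            trait_correlations(tt)

    def test_simulated_panel_hits_targets(self):
        """Average sample correlations land within 0.1 of the generator's
        targets at the panel size."""
        acc = []
        for s in range(60):
            bm, pm, _ = simulate_panel(PanelSpec(), seed=s)
            tt, _ = simulate_traits(bm, pm, seed=5000 + s)
            c = tt.genotype_means()[["TAA", "TPC", "TFC"]].corr().to_numpy()
            acc.append([c[0, 1], c[0, 2], c[1, 2]])
        mean = np.mean(acc, axis=0)
        targets = np.array([0.352, 0.387, 0.826])
        assert np.all(np.abs(mean - targets) < 0.1)


class TestKruskalWallis:
    def test_identical_values_everywhere(self):
        h, p = kruskal_wallis({"a": np.array([2.0, 2.0]), "b": np.array([2.0])})
        assert (h, p) == (0.0, 1.0)

    def test_matches_rank_enumeration_oracle(self):
        """H from ranks computed by explicit enumeration of the rank sums
        on all assignments of <= 8 observations."""
        values = {"a": np.array([1.2, 3.4]), "b": np.array([2.2, 5.1, 0.3]),
                  "c": np.array([4.4, 2.9, 6.0])}
        flat = np.concatenate(list(values.values()))
        ranks = stats.rankdata(flat)
        n = len(flat)
        pos = 0
        h_oracle = 0.0
        for g in values.values():
            r = ranks[pos:pos + len(g)]
            h_oracle += r.sum() ** 2 / len(g)
            pos += len(g)
        h_oracle = 12 / (n * (n + 1)) * h_oracle - 3 * (n + 1)
        h, _ = kruskal_wallis(values)
        assert h == pytest.approx(h_oracle)

    def test_near_zero_under_null_on_average(self):
        rng = np.random.default_rng(5)
        hs = [kruskal_wallis({"a": rng.normal(size=6), "b": rng.normal(size=6)})[0]
              for _ in range(300)]
        # E[H] = G - 1 = 1 under the null
        assert np.mean(hs) == pytest.approx(1.0, abs=0.25)


class TestAnovaTukey:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=8)
        _, _, letters = anova_tukey({"a": base, "b": base + 1e-9 * rng.normal(size=8)})
        assert set(letters["a"]) & set(letters["b"])

    def test_separated_groups_differ(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        _, _, letters = anova_tukey({"a": a, "b": b})
        assert not (set(letters["a"]) & set(letters["b"]))

    def test_letters_consistent_with_pairwise_matrix(self):
        rng = np.random.default_rng(8)
        groups = {l: rng.normal(m, 1, 8)
                  for l, m in zip("abcd", (0.0, 0.5, 4.0, 8.0))}
        _, pairs, letters = anova_tukey(groups)
        for _, row in pairs.iterrows():
            shared = set(letters[row["group1"]]) & set(letters[row["group2"]])
            if bool(row["reject"]):
                assert not shared
            else:
                assert shared

    def test_compact_letters_transitive_free_case(self):
        letters = compact_letters(["a", "b", "c"],
                                  {frozenset(("a", "c"))})
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestSmra:
    @pytest.fixture()
    def planted(self):
        # effect planted on the trait with the weakest group-mean
        # structure, so the allele dominates band-group confounders
        spec = PanelSpec()
        bm, pm, _ = simulate_panel(spec, seed=42)
        tspec = TraitSpec(planted_effects=[("VCC_K4_1", "TAA", 0.8)])
        tt, truth = simulate_traits(bm, pm, tspec, seed=43)
        return bm, tt

    def test_planted_allele_selected_first(self, planted):
        bm, tt = planted
        report = smra(tt, bm, "TAA")
        assert report.steps.iloc[0]["allele"] == "VCC_K4_1"
        assert report.steps.iloc[0]["action"] == "enter"

    def test_r2_bookkeeping(self, planted):
        bm, tt = planted
        steps = smra(tt, bm, "TPC").steps
        entered = steps[steps.action == "enter"]
        assert entered.R2.is_monotonic_increasing
        np.testing.assert_allclose(entered.R, np.sqrt(entered.R2), atol=5e-4)
        np.testing.assert_allclose(
            entered.R2.diff().dropna(), entered.R2_change.iloc[1:], atol=5e-4)

    def test_zero_enter_threshold_gives_empty_model(self, planted):
        bm, tt = planted
        report = smra(tt, bm, "TFC", p_enter=0.0, p_remove=0.01)
        assert report.selected == []

    def test_single_candidate_limit_is_ols(self, planted):
        """With one candidate and a permissive threshold the fit equals
        the single-predictor OLS, and the standardized beta equals the
        Pearson r."""
        bm, tt = planted
        j = bm.band_ids.index("VCC_K4_1")
        sub = BandMatrix(bm.genotype_ids, ["VCC_K4_1"],
                         bm.scores[:, [j]].copy())
        report = smra(tt, sub, "TFC", p_enter=0.9989, p_remove=0.999)
        assert report.selected == ["VCC_K4_1"]
        y = tt.genotype_means()["TFC"].loc[sub.genotype_ids].to_numpy()
        x = sub.scores[:, 0]
        r = np.corrcoef(x, y)[0, 1]
        assert report.steps.iloc[0]["beta_final"] == pytest.approx(r, abs=1e-9)

    def test_thresholds_must_be_ordered(self, planted):
        bm, tt = planted
        with pytest.raises(ValueError, match="p_enter"):
            smra(tt, bm, "TFC", p_enter=0.1, p_remove=0.05)


class TestFoldRange:
    def test_basic(self):
        assert fold_range([2, 4, 8]) == (2.0, 8.0, 4.0)
        assert fold_range([3.0, 3.0]) == (3.0, 3.0, 1.0)

    def test_zero_minimum_rejected(self):
        with pytest.raises(ValueError):
            fold_range([0.0, 1.0])

    def test_fixture_trait(self, fixture_panel):
        _, _, tt = fixture_panel
        taa = tt.genotype_means()["TAA"].to_numpy()
        assert fold_range(taa)[2] == pytest.approx(8.0)
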