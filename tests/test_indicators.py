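"""IndVal indicator analysis, dominance index, multitrophic associations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from baywebs import (
    associate_clusters,
    dominance,
    indval,
    indval_full,
    indval_significance,
    select_dominants,
)


def _toy():
    """Two groups of two samples; taxon abundances chosen by hand."""
    table = pd.DataFrame(
        {
            "perfect": [3.0, 5.0, 0.0, 0.0],  # only in g1, in all its samples
            "partial": [2.0, 2.0, 0.0, 2.0],  # the worked A = 2/3 example
            "absent": [0.0, 0.0, 0.0, 0.0],
        }
    )
    labels = ["g1", "g1", "g2", "g2"]
    return table, labels


class TestIndVal:
    def test_perfect_indicator_scores_one(self):
        table, labels = _toy()
        out = indval(table, labels).set_index("taxon")
        assert out.loc["perfect", "stat"] == pytest.approx(1.0)
        assert out.loc["perfect", "group"] == "g1"

    def test_absent_taxon_scores_zero(self):
        table, labels = _toy()
        out = indval(table, labels).set_index("taxon")
        assert out.loc["absent", "stat"] == 0.0

    def test_absent_from_target_group_scores_zero(self):
        table, labels = _toy()
        full = indval_full(table, labels, combinations="singletons")
        row = full[(full["taxon"] == "perfect") & (full["group"] == "g2")]
        assert row["stat"].iloc[0] == 0.0

    @pytest.mark.parametrize(
        "variant,expected_a",
        [("group_size_corrected", 2 / 3), ("classic", 2 / 3)],
    )
    def test_hand_computed_partial_indicator(self, variant, expected_a):
        """g1 = (2,2), g2 = (0,2): A_g1 = 2/3, B_g1 = 1, stat = sqrt(2/3)."""
        table, labels = _toy()
        full = indval_full(table, labels, variant=variant, combinations="singletons")
        row = full[(full["taxon"] == "partial") & (full["group"] == "g1")].iloc[0]
        assert row["A"] == pytest.approx(expected_a)
        assert row["B"] == pytest.approx(1.0)
        assert row["stat"] == pytest.approx(np.sqrt(expected_a))

    def test_group_size_correction_differs_with_unbalanced_groups(self):
        table = pd.DataFrame({"t": [1.0, 1.0, 1.0, 1.0, 2.0]})
        labels = ["g1"] * 4 + ["g2"]
        corrected = indval_full(table, labels, combinations="singletons")
        classic = indval_full(table, labels, variant="classic", combinations="singletons")
        a_corr = corrected[corrected["group"] == "g2"]["A"].iloc[0]
        a_clas = classic[classic["group"] == "g2"]["A"].iloc[0]
        assert a_corr == pytest.approx(2.0 / 3.0)  # means 1 vs 2
        assert a_clas == pytest.approx(2.0 / 6.0)  # totals 4 vs 2

    def test_specificity_sums_to_one_over_groups(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.random((12, 6)))
        labels = rng.integers(0, 3, 12)
        full = indval_full(table, labels, combinations="singletons")
        sums = full.groupby("taxon")["A"].sum()
        assert np.allclose(sums, 1.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        table, labels = _toy()
        base = indval(table, labels)["stat"].to_numpy()
        scaled = indval(table * c, labels)["stat"].to_numpy()
        assert np.allclose(base, scaled)


class TestIndValSignificance:
    def test_perfect_indicator_attains_lower_bound(self):
        rng = np.random.default_rng(0)
        n = 24
        labels = ["g1"] * (n // 2) + ["g2"] * (n // 2)
        table = pd.DataFrame(
            {"sig": [1.0] * (n // 2) + [0.0] * (n // 2), "noise": rng.random(n)}
        )
        out = indval_significance(table, labels, n_perm=999, seed=1).set_index("taxon")
        assert out.loc["sig", "p"] == pytest.approx(1 / 1000)

    def test_sampled_matches_exhaustive_enumeration(self):
        """5 samples, groups of 2 and 3: only 10 distinct label placements."""
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.random((5, 3)))
        labels = ["a", "a", "b", "b", "b"]
        exact = indval_significance(table, labels, mode="exact").set_index("taxon")

        # independent oracle: enumerate placements, recompute best stat
        def best_stat(lab):
            return indval(table, lab)["stat"].to_numpy()

        obs = best_stat(labels)
        stats_all = []
        for pos in itertools.combinations(range(5), 2):
            lab = np.array(["b"] * 5, dtype=object)
            lab[list(pos)] = "a"
            stats_all.append(best_stat(lab))
        stats_all = np.array(stats_all)
        p_oracle = (stats_all >= obs - 1e-12).mean(axis=0)
        assert np.allclose(exact["p"].to_numpy(), p_oracle)

        sampled = indval_significance(table, labels, n_perm=4999, seed=0)
        assert np.abs(sampled["p"].to_numpy() - p_oracle).max() < 0.03

    def test_null_p_values_uniform(self):
        """Labels independent of the data: p approximately uniform over taxa."""
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.random((20, 500)))
        labels = rng.integers(0, 2, 20)
        out = indval_significance(table, labels, n_perm=199, seed=4)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01


class TestDominance:
    def _fixture(self):
        """Cluster of 4 samples; focal taxon relative densities .5,.25,.25,0."""
        table = pd.DataFrame(
            {"focal": [2.0, 1.0, 1.0, 0.0], "rest": [2.0, 3.0, 3.0, 4.0]}
        )
        labels = ["j"] * 4
        return table, labels

    def test_hand_computed_record(self):
        table, labels = self._fixture()
        rec = dominance(table, labels).set_index("taxon")
        assert rec.loc["focal", "F"] == pytest.approx(75.0)
        assert rec.loc["focal", "D"] == pytest.approx(0.25)
        assert rec.loc["focal", "Dprime"] == pytest.approx(1875.0)

    def test_formula_ceiling(self):
        table = pd.DataFrame({"only": [1.0, 2.0, 3.0]})
        rec = dominance(table, ["j"] * 3).iloc[0]
        assert rec["F"] == 100.0 and rec["D"] == 1.0 and rec["Dprime"] == 10_000.0

    def test_absent_taxon_zeroes(self):
        table = pd.DataFrame({"here": [1.0, 1.0], "gone": [0.0, 0.0]})
        rec = dominance(table, ["j", "j"]).set_index("taxon")
        assert rec.loc["gone", "F"] == 0.0 and rec.loc["gone", "Dprime"] == 0.0

    def test_zero_total_sample_warns(self):
        table = pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        with pytest.warns(UserWarning, match="zero total"):
            dominance(table, ["j", "j"])

    def test_boundary_frequency_excluded(self):
        """F exactly 50% fails the strict >50% rule even with huge density."""
        table = pd.DataFrame(
            {
                "half": [9.0, 9.0, 0.0, 0.0],  # 2 of 4 samples -> F = 50
                "low1": [1.0, 1.0, 1.0, 1.0],
                "low2": [0.5, 0.5, 1.0, 1.0],
            }
        )
        rec = select_dominants(dominance(table, ["j"] * 4)).set_index("taxon")
        assert rec.loc["half", "F"] == 50.0
        assert not rec.loc["half", "dominant"]

    def test_single_present_taxon_degenerate(self):
        table = pd.DataFrame({"solo": [1.0, 1.0], "void": [0.0, 0.0]})
        rec = select_dominants(dominance(table, ["j", "j"])).set_index("taxon")
        assert not rec.loc["solo", "dominant"]
        assert rec.loc["solo", "degenerate"]

    def test_median_rule_selects_high_density_taxa(self):
        table = pd.DataFrame(
            {
                "big": [10.0, 10.0, 10.0, 10.0],
                "mid": [2.0, 2.0, 2.0, 2.0],
                "small": [1.0, 1.0, 1.0, 1.0],
            }
        )
        rec = select_dominants(dominance(table, ["j"] * 4)).set_index("taxon")
        assert rec.loc["big", "dominant"]
        assert not rec.loc["small", "dominant"]


class TestAssociations:
    def _index(self):
        return pd.MultiIndex.from_product(
            [["e1", "e2", "b1", "b2"], ["S1", "S2"]], names=["site", "season"]
        )

    def test_single_group_is_its_own_partition(self):
        idx = self._index()
        labels = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=idx)
        out = associate_clusters({"benthos": labels})
        assert (out["benthos_cluster"] == labels).all()
        assert out["association"].nunique() == 2

    def test_two_region_design_gives_two_types(self):
        idx = self._index()
        spatial = [1, 1, 1, 1, 2, 2, 2, 2]
        parts = {
            g: pd.Series(spatial, index=idx) for g in ("plankton", "benthos", "nekton")
        }
        out = associate_clusters(parts)
        assert out["association"].nunique() == 2

    def test_dominant_taxa_union(self):
        idx = self._index()
        parts = {
            "plankton": pd.Series([1] * 4 + [2] * 4, index=idx),
            "benthos": pd.Series(["x"] * 4 + ["y"] * 4, index=idx),
        }
        dominants = {
            "plankton": {1: ("p1", "p2"), 2: ("p3",)},
            "benthos": {"x": ("b1",), "y": ("b2",)},
        }
        out = associate_clusters(parts, dominants)
        assert out["dominant_taxa"].iloc[0] == ("b1", "p1", "p2")
        assert out["dominant_taxa"].iloc[-1] == ("b2", "p3")

    def test_key_mismatch_is_error(self):
        idx = self._index()
        other = pd.MultiIndex.from_product(
            [["z1"], ["S9"]], names=["site", "season"]
        )
        with pytest.raises(ValueError, match="share no"):
            associate_clusters(
                {
                    "a": pd.Series([1] * len(idx), index=idx),
                    "b": pd.Series([1], index=other),
                }
            )
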