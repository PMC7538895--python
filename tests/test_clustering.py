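"""Ward unit clustering, MRPP permutation tests, nonparametric contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from baywebs import (
    KohonenSOM,
    assign_samples,
    kruskal_wallis,
    mrpp,
    pairwise_mann_whitney,
    ward_cluster_units,
)


def _som_with_codebook(code, rows, cols):
    som = KohonenSOM(rows, cols)
    som.codebook_ = np.asarray(code, dtype=float)
    som.grid_coordinates_ = som._grid_coords()
    som.n_features_in_ = som.codebook_.shape[1]
    return som


def _ward_oracle_partitions(points):
    """Greedy minimum-variance agglomeration by exhaustive pair search.

    Independent of scipy: at each step every cluster pair is scored by the
    exact increase in total within-cluster sum of squares and the smallest
    merge is taken.  Returns the partition (as label arrays) at every k.
    """
    clusters = [[i] for i in range(len(points))]
    partitions = {}

    def ess(idx):
        sub = points[idx]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    while True:
        labels = np.empty(len(points), dtype=int)
        for ci, members in enumerate(clusters):
            labels[members] = ci
        partitions[len(clusters)] = labels
        if len(clusters) == 1:
            break
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            delta = (
                ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j])
            )
            if best is None or delta < best[0] - 1e-12:
                best = (delta, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return partitions


class TestWard:
    def test_two_blobs(self):
        rng = np.random.default_rng(0)
        code = np.vstack([rng.normal(0, 0.1, (8, 3)), rng.normal(5, 0.1, (8, 3))])
        som = _som_with_codebook(code, 4, 4)
        part = ward_cluster_units(som, 2)
        assert adjusted_rand_score(part.unit_labels, [0] * 8 + [1] * 8) == 1.0

    def test_singletons_and_bad_k(self):
        code = np.random.default_rng(1).random((6, 2))
        som = _som_with_codebook(code, 2, 3)
        assert len(set(ward_cluster_units(som, 6).unit_labels)) == 6
        with pytest.raises(ValueError):
            ward_cluster_units(som, 0)
        with pytest.raises(ValueError):
            ward_cluster_units(som, 7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_minimum_variance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        code = rng.random((7, 3))
        som = _som_with_codebook(code, 1, 7)  # lattice shape irrelevant to Ward
        som.n_rows, som.n_cols = 1, 7
        oracle = _ward_oracle_partitions(code)
        for k in range(1, 8):
            part = ward_cluster_units(som, k)
            assert adjusted_rand_score(part.unit_labels, oracle[k]) == 1.0

    def test_unit_order_invariance(self):
        rng = np.random.default_rng(3)
        code = rng.random((9, 4))
        perm = rng.permutation(9)
        p1 = ward_cluster_units(_som_with_codebook(code, 3, 3), 3).unit_labels
        p2 = ward_cluster_units(_som_with_codebook(code[perm], 3, 3), 3).unit_labels
        # map the permuted-unit labels back to the original unit order
        assert adjusted_rand_score(p1, p2[np.argsort(perm)]) == 1.0


class TestAssignment:
    def test_sample_equal_to_codebook(self):
        code = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0], [6.0, 6.0]])
        som = _som_with_codebook(code, 2, 2)
        part = ward_cluster_units(som, 2)
        labels = assign_samples(som, code[[2]], part)
        assert labels.iloc[0] == part.unit_labels[2]

    def test_relabeling_equivariance(self, trained_planted_som):
        som, scaled, _ = trained_planted_som
        part = ward_cluster_units(som, 2)
        labels = assign_samples(som, scaled, part)
        swapped = part.relabel({1: 2, 2: 1})
        labels2 = assign_samples(som, scaled, swapped)
        assert (labels2 == labels.map({1: 2, 2: 1})).all()

    def test_dimension_mismatch(self, trained_planted_som):
        som, scaled, _ = trained_planted_som
        part = ward_cluster_units(som, 2)
        with pytest.raises(ValueError):
            assign_samples(som, scaled.to_numpy()[:, :2], part)

    def test_planted_clusters_recovered(self, trained_planted_som):
        som, scaled, planted = trained_planted_som
        part = ward_cluster_units(som, 2)
        labels = assign_samples(som, scaled, part)
        assert adjusted_rand_score(planted.to_numpy(), labels.to_numpy()) > 0.9


def _mrpp_oracle(dmat, labels):
    """Brute-force MRPP over all distinct label placements (test-local)."""
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)

    def delta(lab):
        tot = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            pair = [dmat[i, j] for i, j in itertools.combinations(idx, 2)]
            tot += len(idx) / n * float(np.mean(pair))
        return tot

    deltas = []
    for positions in itertools.permutations(range(n)):
        lab = np.empty(n, dtype=labels.dtype)
        start = 0
        for g, c in zip(uniq, counts):
            lab[list(positions[start : start + c])] = g
            start += c
        deltas.append(delta(lab))
    deltas = np.asarray(deltas)
    obs = delta(labels)
    return obs, float(np.mean(deltas <= obs + 1e-12)), float(deltas.mean())


class TestMRPP:
    def test_perfect_separation(self):
        x = np.array([[0.0], [0.0], [0.0], [9.0], [9.0], [9.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = mrpp(x, labels, mode="exact")
        assert res.A == pytest.approx(1.0)
        # the minimum attainable exact p: only the two block placements
        assert res.p == pytest.approx(2 / 20)

    def test_exact_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = mrpp(x, labels, mode="exact")
        dmat = squareform(pdist(x))
        obs, p_oracle, mean_delta = _mrpp_oracle(dmat, labels)
        assert res.delta_observed == pytest.approx(obs)
        assert res.p == pytest.approx(p_oracle)

    def test_sampled_converges_to_exact(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(1.5, 1, (4, 2))])
        labels = np.array([0] * 4 + [1] * 4)
        exact = mrpp(x, labels, mode="exact")
        sampled = mrpp(x, labels, n_perm=10_000, seed=0)
        se = np.sqrt(exact.p * (1 - exact.p) / 10_000)
        assert abs(sampled.p - exact.p) <= 3 * se + 1e-4

    def test_scale_invariance_of_A(self):
        rng = np.random.default_rng(6)
        x = rng.random((10, 3))
        labels = np.array([0, 1] * 5)
        a1 = mrpp(x, labels, n_perm=99).A
        a2 = mrpp(x * 37.0, labels, n_perm=99).A
        assert a1 == pytest.approx(a2)

    def test_accepts_distance_matrix(self):
        rng = np.random.default_rng(7)
        x = rng.random((8, 2))
        labels = np.array([0] * 4 + [1] * 4)
        d = squareform(pdist(x))
        assert mrpp(d, labels, n_perm=99, seed=1).delta_observed == pytest.approx(
            mrpp(x, labels, n_perm=99, seed=1).delta_observed
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            mrpp(np.random.rand(4, 2), [0, 0, 0, 0])
        with pytest.raises(ValueError, match="at least two members"):
            mrpp(np.random.rand(4, 2), [0, 0, 0, 1])
        with pytest.raises(ValueError, match="identical"):
            mrpp(np.ones((6, 2)), [0, 0, 0, 1, 1, 1])


class TestRankTests:
    def test_identical_groups(self):
        h, p = kruskal_wallis([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        h, p = kruskal_wallis([5, 5, 5, 5], [0, 0, 1, 1])
        assert (h, p) == (0.0, 1.0)

    def test_complete_separation_exact_p(self):
        """Groups (1,2,3) vs (4,5,6): U = 0, one-sided exact p = 1/20."""
        table = pairwise_mann_whitney(
            [1, 2, 3, 4, 5, 6],
            ["a", "a", "a", "b", "b", "b"],
            alternative="less",
            method="exact",
        )
        assert table["U"].iloc[0] == 0.0
        assert table["p"].iloc[0] == pytest.approx(0.05)

    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [rng.normal(0, 1, 20 * 4), rng.normal(3.0, 1, 20)]
        )
        labels = np.repeat(list("ABCDE"), 20)
        h, p = kruskal_wallis(values, labels)
        assert p < 0.001

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(i, 1, 10) for i in range(3)])
        labels = np.repeat(["a", "b", "c"], 10)
        table = pairwise_mann_whitney(values, labels, adjust="holm")
        assert (table["p_adj"] >= table["p"] - 1e-12).all()
        assert len(table) == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])
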