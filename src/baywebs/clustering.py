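"""Clustering of SOM units and significance testing of community groups.

Trained SOM units are grouped by Ward's minimum-variance hierarchical
clustering of their codebook vectors; samples inherit the cluster of their
best matching unit.  Group differences are tested with the multi-response
permutation procedure (MRPP), and environmental contrasts with the
Kruskal-Wallis and pairwise Mann-Whitney tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterPartition",
    "MRPPResult",
    "ward_cluster_units",
    "assign_samples",
    "mrpp",
    "kruskal_wallis",
    "pairwise_mann_whitney",
]


@dataclass
class ClusterPartition:
    """Cluster labels for SOM units (and, once assigned, for samples)."""

    unit_labels: np.ndarray  # one label in 1..k per SOM unit
    k: int
    linkage: np.ndarray
    sample_labels: pd.Series | None = None

    def relabel(self, mapping: dict) -> "ClusterPartition":
        units = np.array([mapping[l] for l in self.unit_labels])
        samples = (
            self.sample_labels.map(mapping) if self.sample_labels is not None else None
        )
        return ClusterPartition(units, self.k, self.linkage, samples)


def ward_cluster_units(som, k: int) -> ClusterPartition:
    """Ward/Euclidean agglomerative clustering of the unit codebooks, cut at k.

    Empty units (no mapped samples) participate like any other unit: the
    hierarchy is built on the codebooks themselves.  Deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    code = np.asarray(som.codebook_, dtype=float)
    if k > len(code):
        raise ValueError(f"k={k} exceeds the {len(code)} SOM units")
    z = linkage(code, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterPartition(unit_labels=labels, k=k, linkage=z)


def assign_samples(som, matrix, partition: ClusterPartition) -> pd.Series:
    """Label every sample with the cluster of its best matching unit."""
    if isinstance(matrix, pd.DataFrame):
        index, x = matrix.index, matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(len(x))
    bmu = som.predict(x)
    labels = pd.Series(partition.unit_labels[bmu], index=index, name="cluster")
    partition.sample_labels = labels
    return labels


@dataclass
class MRPPResult:
    A: float
    delta_observed: float
    expected_delta: float
    p: float
    n_perm: int
    mode: str


def _weighted_within_delta(dmat: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    delta = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = dmat[np.ix_(idx, idx)]
        m = len(idx)
        mean_within = sub[np.triu_indices(m, k=1)].mean()
        delta += (m / n) * mean_within
    return delta


def _distinct_assignments(labels: np.ndarray):
    """All distinct placements of the label multiset over the n positions."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)

    def rec(positions, groups):
        if not groups:
            yield ()
            return
        g, c = groups[0]
        for chosen in itertools.combinations(positions, c):
            rest = tuple(p for p in positions if p not in chosen)
            for tail in rec(rest, groups[1:]):
                yield ((g, chosen),) + tail

    for assignment in rec(tuple(range(n)), list(zip(uniq, counts))):
        out = np.empty(n, dtype=labels.dtype)
        for g, pos in assignment:
            out[list(pos)] = g
        yield out


def _n_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def mrpp(
    data,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
    mode: str = "sampled",
    metric: str = "euclidean",
) -> MRPPResult:
    """Multi-response permutation procedure.

    ``data`` is either a samples x features matrix or a square distance
    matrix.  The observed statistic is the group-size-weighted mean
    within-group distance delta = sum_j (n_j/N) * mean within-group distance.
    The chance-corrected agreement is A = 1 - delta_obs / E[delta], with
    E[delta] the exact expectation under random relabelling (the overall mean
    pairwise distance).  The sampled p-value uses the add-one estimator
    p = (1 + #{delta_perm <= delta_obs}) / (1 + n_perm); exact mode enumerates
    every distinct label arrangement (refused above 10 000).
    """
    labels = np.asarray(pd.Series(labels).to_numpy())
    x = np.asarray(data, dtype=float)
    if x.ndim == 2 and x.shape[0] == x.shape[1] and np.allclose(x, x.T):
        dmat = x.copy()
    else:
        dmat = squareform(pdist(x, metric=metric))
    n = dmat.shape[0]
    if len(labels) != n:
        raise ValueError("labels do not match the data")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("MRPP needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    off_diag = dmat[np.triu_indices(n, k=1)]
    if np.all(off_diag == 0):
        raise ValueError("all points identical: MRPP A is undefined")

    delta_obs = _weighted_within_delta(dmat, labels)
    expected = float(off_diag.mean())
    a = 1.0 - delta_obs / expected

    if mode == "exact":
        total = _n_arrangements(labels)
        if total > 10_000:
            raise ValueError(
                f"{total} label arrangements exceed the exact-mode limit of 10000"
            )
        deltas = np.array(
            [_weighted_within_delta(dmat, perm) for perm in _distinct_assignments(labels)]
        )
        p = float(np.mean(deltas <= delta_obs + 1e-12))
        return MRPPResult(a, delta_obs, expected, p, total, "exact")

    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _weighted_within_delta(dmat, perm) <= delta_obs + 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MRPPResult(a, delta_obs, expected, p, n_perm, "sampled")


def _split_groups(values, labels):
    values = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    labels = np.asarray(pd.Series(labels).to_numpy())
    groups = []
    names = []
    for g in pd.unique(labels):
        grp = values[labels == g]
        if grp.size == 0:
            raise ValueError(f"group {g!r} is empty")
        groups.append(grp)
        names.append(g)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    return names, groups


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction; (0, 1) if all values tie."""
    _, groups = _split_groups(values, labels)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            h, p = stats.kruskal(*groups)
    except ValueError:
        # every observation identical: no evidence of any difference
        return 0.0, 1.0
    if np.isnan(h):
        return 0.0, 1.0
    return float(h), float(p)


def pairwise_mann_whitney(
    values,
    labels,
    alternative: str = "two-sided",
    adjust: str | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Mann-Whitney U for every pair of groups, optionally Holm-adjusted.

    Field practice for these contrasts leaves p-values unadjusted; pass
    ``adjust='holm'`` for a step-down familywise correction.
    """
    names, groups = _split_groups(values, labels)
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(groups), 2):
        u, p = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
        rows.append({"group1": names[i], "group2": names[j], "U": float(u), "p": float(p)})
    table = pd.DataFrame(rows)
    if adjust is not None:
        if adjust != "holm":
            raise ValueError(f"unsupported adjustment {adjust!r}")
        table["p_adj"] = multipletests(table["p"], method="holm")[1]
    return table
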