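"""Indicator species (IndVal) and dominant-taxon selection.

IndVal associates each taxon with the cluster (or cluster combination) where
it is both concentrated (specificity A) and reliably present (fidelity B);
the reported statistic is sqrt(A*B), significance by Monte Carlo label
permutation.  Dominance combines occurrence frequency with mean relative
density: D'_ij = F_ij * D_ij * 100, with F_ij = (P_ij / P_j) * 100 the
percent of cluster-j samples containing taxon i and
D_ij = [sum_k N_ik / N_k] / P_j the mean relative density.  Dominant taxa
have F_ij > 50 and D_ij above the within-cluster median of present taxa.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "indval",
    "indval_full",
    "indval_significance",
    "dominance",
    "select_dominants",
    "associate_clusters",
]


def _as_matrix(table):
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    x = np.asarray(table, dtype=float)
    return x, list(range(x.shape[1]))


def _combo_name(combo) -> str:
    return "+".join(str(g) for g in combo)


def _indval_matrix(x, labels, groups, combos, variant):
    """(A, B, stat) arrays of shape (n_combos, n_taxa)."""
    presence = x > 0
    per_group_mean = np.stack([x[labels == g].mean(axis=0) for g in groups])
    per_group_sum = np.stack([x[labels == g].sum(axis=0) for g in groups])
    basis = per_group_mean if variant == "group_size_corrected" else per_group_sum
    denom = basis.sum(axis=0)  # per taxon

    a = np.zeros((len(combos), x.shape[1]))
    b = np.zeros_like(a)
    for ci, combo in enumerate(combos):
        mask = np.isin(labels, combo)
        with np.errstate(invalid="ignore", divide="ignore"):
            a[ci] = np.where(
                denom > 0,
                basis[[groups.index(g) for g in combo]].sum(axis=0) / denom,
                0.0,
            )
        b[ci] = presence[mask].mean(axis=0)
    return a, b, np.sqrt(a * b)


def _indval_stats(x, labels, groups, combos, variant):
    """Per-taxon best (combo, A, B, stat). Returns arrays over taxa."""
    a, b, stat = _indval_matrix(x, labels, groups, combos, variant)
    best = np.argmax(stat, axis=0)
    cols = np.arange(x.shape[1])
    return best, a[best, cols], b[best, cols], stat[best, cols]


def _make_combos(groups, combinations):
    combos = [(g,) for g in groups]
    if combinations == "pairs":
        combos += list(itertools.combinations(groups, 2))
    elif combinations == "all":
        for r in range(2, len(groups)):
            combos += list(itertools.combinations(groups, r))
    elif combinations != "singletons":
        raise ValueError(f"unknown combinations mode {combinations!r}")
    # the full set of groups is excluded: it carries no indicator information
    return [c for c in combos if len(c) < len(groups) or len(groups) == 1]


def indval(
    table,
    labels,
    variant: str = "group_size_corrected",
    combinations: str = "pairs",
) -> pd.DataFrame:
    """Indicator value per taxon, reported for its best cluster combination.

    ``variant='group_size_corrected'`` (the IndVal.g form) builds specificity
    from per-group mean abundances so unequal cluster sizes do not bias A;
    ``variant='classic'`` uses raw group totals.  Candidate target groups are
    single clusters plus, by default, all pairs ('singletons', 'pairs' or
    'all').  stat = sqrt(A*B) is 1 exactly when a taxon occurs only inside the
    target combination and in every one of its samples.
    """
    if variant not in ("group_size_corrected", "classic"):
        raise ValueError(f"unknown variant {variant!r}")
    x, taxa = _as_matrix(table)
    labels = np.asarray(pd.Series(labels).to_numpy())
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("IndVal needs at least two clusters")
    combos = _make_combos(groups, combinations)
    best_combo, a, b, stat = _indval_stats(x, labels, groups, combos, variant)
    return pd.DataFrame(
        {
            "taxon": taxa,
            "group": [_combo_name(combos[c]) for c in best_combo],
            "A": a,
            "B": b,
            "stat": stat,
        }
    )


def indval_full(
    table,
    labels,
    variant: str = "group_size_corrected",
    combinations: str = "pairs",
) -> pd.DataFrame:
    """A, B and stat for every (taxon, candidate group combination)."""
    x, taxa = _as_matrix(table)
    labels = np.asarray(pd.Series(labels).to_numpy())
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("IndVal needs at least two clusters")
    combos = _make_combos(groups, combinations)
    a, b, stat = _indval_matrix(x, labels, groups, combos, variant)
    rows = []
    for ci, combo in enumerate(combos):
        for ti, taxon in enumerate(taxa):
            rows.append(
                {
                    "taxon": taxon,
                    "group": _combo_name(combo),
                    "A": a[ci, ti],
                    "B": b[ci, ti],
                    "stat": stat[ci, ti],
                }
            )
    return pd.DataFrame(rows)


def indval_significance(
    table,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
    variant: str = "group_size_corrected",
    combinations: str = "pairs",
    mode: str = "sampled",
) -> pd.DataFrame:
    """Permutation p-value per taxon for its best IndVal statistic.

    Sampled mode permutes labels Monte Carlo style with the add-one estimator
    p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm); exact mode enumerates
    every distinct label arrangement (refused above 10 000) and reports the
    proportion with stat >= stat_obs.
    """
    x, taxa = _as_matrix(table)
    labels = np.asarray(pd.Series(labels).to_numpy())
    groups = sorted(pd.unique(labels).tolist())
    combos = _make_combos(groups, combinations)
    _, a, b, stat_obs = _indval_stats(x, labels, groups, combos, variant)
    out = indval(table, labels, variant=variant, combinations=combinations)

    if mode == "exact":
        from .clustering import _distinct_assignments, _n_arrangements

        total = _n_arrangements(labels)
        if total > 10_000:
            raise ValueError(
                f"{total} label arrangements exceed the exact-mode limit of 10000"
            )
        exceed = np.zeros_like(stat_obs)
        for perm in _distinct_assignments(labels):
            _, _, _, stat_perm = _indval_stats(x, perm, groups, combos, variant)
            exceed += stat_perm >= stat_obs - 1e-12
        out["p"] = exceed / total
        return out

    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(stat_obs)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, _, _, stat_perm = _indval_stats(x, perm, groups, combos, variant)
        exceed += stat_perm >= stat_obs - 1e-12
    out["p"] = (1 + exceed) / (1 + n_perm)
    return out


def dominance(table, labels) -> pd.DataFrame:
    """Dominance records (F_ij, D_ij, D'_ij) for every taxon x cluster.

    Samples whose total density is zero are excluded from the mean relative
    density with a warning (they carry no compositional information).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float))
    labels = pd.Series(np.asarray(pd.Series(labels).to_numpy()), index=table.index)
    totals = table.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} sample(s) with zero total density "
            "excluded from relative densities",
            stacklevel=2,
        )
    rel = table.div(totals.replace(0, np.nan), axis=0)

    rows = []
    for cluster in sorted(pd.unique(labels).tolist()):
        in_cluster = labels == cluster
        p_j = int(in_cluster.sum())
        if p_j == 0:
            raise ValueError(f"cluster {cluster!r} is empty")
        sub = table.loc[in_cluster]
        sub_rel = rel.loc[in_cluster].fillna(0.0)
        p_ij = (sub > 0).sum(axis=0)
        f_ij = p_ij / p_j * 100.0
        d_ij = sub_rel.sum(axis=0) / p_j
        for taxon in table.columns:
            rows.append(
                {
                    "taxon": taxon,
                    "cluster": cluster,
                    "P_ij": int(p_ij[taxon]),
                    "P_j": p_j,
                    "F": float(f_ij[taxon]),
                    "D": float(d_ij[taxon]),
                    "Dprime": float(f_ij[taxon] * d_ij[taxon] * 100.0),
                }
            )
    return pd.DataFrame(rows)


def select_dominants(records: pd.DataFrame) -> pd.DataFrame:
    """Flag dominant taxa: F > 50 (strict) and D above the cluster median.

    The median of D is taken over taxa actually present in the cluster
    (P_ij > 0); with a single present taxon nothing can exceed its own median
    and the cluster is flagged degenerate.
    """
    records = records.copy()
    records["dominant"] = False
    records["degenerate"] = False
    for cluster, sub in records.groupby("cluster"):
        present = sub[sub["P_ij"] > 0]
        if present.empty:
            continue
        if len(present) == 1:
            records.loc[present.index, "degenerate"] = True
            continue
        med = present["D"].median()
        dom = (present["F"] > 50.0) & (present["D"] > med)
        records.loc[present.index[dom], "dominant"] = True
    return records


def associate_clusters(
    partitions: dict[str, pd.Series],
    dominants: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Combine per-taxonomic-group sample labels into multitrophic associations.

    ``partitions`` maps a taxonomic group name to its sample-label Series,
    all keyed by the same (site, season) index.  Each overlapping sample gets
    the tuple of per-group cluster labels ('association'); if per-group
    dominant-taxa lists are supplied, their union is attached per sample.
    """
    if not partitions:
        raise ValueError("no partitions supplied")
    names = list(partitions)
    frame = pd.concat(
        {name: partitions[name] for name in names}, axis=1, join="inner"
    )
    if frame.empty:
        raise ValueError("partitions share no (site, season) samples")
    frame.columns = [f"{name}_cluster" for name in names]
    frame["association"] = [
        "|".join(f"{n}:{frame.iloc[i][f'{n}_cluster']}" for n in names)
        for i in range(len(frame))
    ]
    if dominants is not None:
        taxa_col = []
        for i in range(len(frame)):
            union: set = set()
            for n in names:
                cluster = frame.iloc[i][f"{n}_cluster"]
                union |= set(dominants.get(n, {}).get(cluster, ()))
            taxa_col.append(tuple(sorted(map(str, union))))
        frame["dominant_taxa"] = taxa_col
    return frame
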