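"""Synthetic multitrophic survey data with known ground truth.

Emulates a two-channel (estuarine vs deep-bay) seasonal survey: clustered
abundance structure with optional seasonal taxon turnover, environmental
gradients tied to the planted clusters, and consumer isotope signatures
generated as TEF-shifted mixtures of source signatures with Gaussian noise.
Every generator is a pure function of its scenario and seed.

Abundance units are arbitrary densities: real surveys standardize nets,
grabs and trawls differently per taxonomic group and never reconcile them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mixing import TefSet

__all__ = [
    "CommunityScenario",
    "SourceSpec",
    "IsotopeScenario",
    "generate_community",
    "generate_environment",
    "generate_isotopes",
    "two_region_scenario",
]


def _lookup(param, taxon, cluster, default=None):
    """Resolve a scalar or {(taxon, cluster)|taxon: value} parameter."""
    if isinstance(param, dict):
        for key in ((taxon, cluster), taxon):
            if key in param:
                return param[key]
        if default is not None:
            return default
        raise KeyError(f"no value for ({taxon}, {cluster})")
    return param


@dataclass
class CommunityScenario:
    """Planted-cluster community design.

    ``site_clusters`` assigns every site to exactly one cluster (the planted
    label of all its samples).  Abundances are log-normal magnitudes gated by
    Bernoulli detection; per-(taxon, cluster) overrides of the log-mean,
    log-sigma and detection probability are given as dicts.  ``turnover`` is
    the per-season fraction of each cluster's active taxa pool that is
    replaced (0 = seasonally stable, as for benthos/nekton; plankton pools
    turn over).
    """

    site_clusters: dict[str, str]  # site -> cluster
    taxa_pools: dict[str, tuple[str, ...]]  # cluster -> taxa
    n_seasons: int = 6
    abundance_mean: float | dict = 2.0  # log-scale
    abundance_sigma: float | dict = 0.5
    detection_prob: float | dict = 0.9
    turnover: float = 0.0
    seed: int = 0

    def __post_init__(self):
        clusters = set(self.site_clusters.values())
        for c in clusters:
            if not self.taxa_pools.get(c):
                raise ValueError(f"empty taxa pool for cluster {c!r}")
        for c, pool in self.taxa_pools.items():
            for t in pool:
                sig = _lookup(self.abundance_sigma, t, c, default=0.0)
                if sig < 0:
                    raise ValueError("abundance sigma must be >= 0")
                p = _lookup(self.detection_prob, t, c, default=1.0)
                if not 0.0 <= p <= 1.0:
                    raise ValueError("detection probabilities must be in [0, 1]")
        if not 0.0 <= self.turnover <= 1.0:
            raise ValueError("turnover must be in [0, 1]")
        if self.n_seasons < 1:
            raise ValueError("need at least one season")


def _seasonal_pools(pool, n_seasons, turnover, rng):
    """Sliding-window rotation of the cluster pool across seasons."""
    pool = list(pool)
    m = len(pool)
    if turnover == 0 or m == 1:
        return [tuple(pool)] * n_seasons
    order = list(rng.permutation(pool))
    window = max(1, round(m * (1.0 - turnover)))
    step = max(1, round(turnover * window))
    pools = []
    start = 0
    for _ in range(n_seasons):
        active = tuple(order[(start + i) % m] for i in range(window))
        pools.append(active)
        start += step
    return pools


def generate_community(
    scenario: CommunityScenario,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a wide (site, season) x taxa density table plus planted labels.

    Densities are >= 0; a record exists for every (site, season); identical
    seeds give byte-identical tables.
    """
    rng = np.random.default_rng(scenario.seed)
    sites = sorted(scenario.site_clusters)
    seasons = [f"S{t + 1}" for t in range(scenario.n_seasons)]
    clusters = sorted(set(scenario.site_clusters.values()))
    all_taxa = sorted({t for pool in scenario.taxa_pools.values() for t in pool})
    col_of = {t: j for j, t in enumerate(all_taxa)}

    pools_by_cluster = {
        c: _seasonal_pools(
            scenario.taxa_pools[c], scenario.n_seasons, scenario.turnover, rng
        )
        for c in clusters
    }

    index = pd.MultiIndex.from_product([sites, seasons], names=["site", "season"])
    data = np.zeros((len(index), len(all_taxa)))
    labels = []
    for i, (site, season) in enumerate(index):
        cluster = scenario.site_clusters[site]
        labels.append(cluster)
        t = seasons.index(season)
        for taxon in pools_by_cluster[cluster][t]:
            p = _lookup(scenario.detection_prob, taxon, cluster, default=1.0)
            detected = rng.random() < p if p < 1.0 else True
            mu = _lookup(scenario.abundance_mean, taxon, cluster, default=2.0)
            sig = _lookup(scenario.abundance_sigma, taxon, cluster, default=0.0)
            density = float(np.exp(mu + sig * rng.standard_normal())) if detected else 0.0
            data[i, col_of[taxon]] = density
    table = pd.DataFrame(data, index=index, columns=all_taxa)
    planted = pd.Series(labels, index=index, name="planted_cluster")
    return table, planted


def generate_environment(
    labels: pd.Series,
    cluster_medians: pd.DataFrame | dict,
    dispersion: float | dict = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample environmental values drawn around each cluster's median.

    ``cluster_medians`` is a variables x clusters table (or nested dict
    variable -> {cluster: median}); ``dispersion`` is the Gaussian SD, a
    scalar or per-variable dict.  dispersion = 0 reproduces the medians
    exactly.  A sample whose cluster lacks a median is a configuration error.
    """
    medians = pd.DataFrame(cluster_medians)
    rng = np.random.default_rng(seed)
    out = {}
    for var in medians.index:
        sd = dispersion[var] if isinstance(dispersion, dict) else dispersion
        if sd < 0:
            raise ValueError("dispersion must be >= 0")
        row = medians.loc[var]
        missing = set(labels.unique()) - set(row.dropna().index)
        if missing:
            raise ValueError(f"no median of {var!r} for cluster(s) {sorted(missing)}")
        centres = labels.map(row).astype(float)
        out[var] = centres + sd * rng.standard_normal(len(labels))
    return pd.DataFrame(out, index=labels.index)


@dataclass(frozen=True)
class SourceSpec:
    """One organic-matter source signature (mean +/- SD per isotope, permil)."""

    name: str
    d13c_mean: float
    d13c_sd: float
    d15n_mean: float
    d15n_sd: float

    def __post_init__(self):
        if self.d13c_sd < 0 or self.d15n_sd < 0:
            raise ValueError("source SDs must be >= 0")


@dataclass
class IsotopeScenario:
    """Forward model for consumer isotope signatures.

    Each consumer group draws its expected signature as the
    ``true_proportions``-weighted mean of the source means, shifted by one
    trophic step of enrichment (primary or carnivore d15N, per
    ``consumer_level``), with independent Gaussian noise per isotope.
    """

    sources: tuple[SourceSpec, ...]
    true_proportions: dict[str, tuple[float, ...]]  # consumer group -> simplex
    tef: TefSet = field(default_factory=TefSet)
    consumer_level: dict[str, str] | str = "primary"
    noise_sd: tuple[float, float] = (0.3, 0.3)  # (d13C, d15N)
    n_per_group: int = 10
    n_per_source: int = 10
    seed: int = 0

    def __post_init__(self):
        if len(self.sources) < 1:
            raise ValueError("need at least one source")
        for group, p in self.true_proportions.items():
            p = np.asarray(p, dtype=float)
            if len(p) != len(self.sources):
                raise ValueError(f"proportions of {group!r} do not match sources")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"proportions of {group!r} are not on the simplex")
        if min(self.noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")

    def level_of(self, group: str) -> str:
        if isinstance(self.consumer_level, dict):
            return self.consumer_level.get(group, "primary")
        return self.consumer_level


def generate_isotopes(scenario: IsotopeScenario) -> pd.DataFrame:
    """Specimen-level isotope table for sources and consumers.

    Columns: group, taxon, specimen_id, d13C, d15N, role in {source, consumer}.
    Source specimens are drawn from each source's Gaussian law; consumer
    specimens follow delta = sum_i p_i * delta_source_i + TEF + noise per
    isotope.  Deterministic per seed.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for src in scenario.sources:
        for i in range(scenario.n_per_source):
            rows.append(
                {
                    "group": src.name,
                    "taxon": src.name,
                    "specimen_id": f"{src.name}-{i + 1}",
                    "d13C": src.d13c_mean + src.d13c_sd * rng.standard_normal(),
                    "d15N": src.d15n_mean + src.d15n_sd * rng.standard_normal(),
                    "role": "source",
                }
            )
    mu13 = np.array([s.d13c_mean for s in scenario.sources])
    mu15 = np.array([s.d15n_mean for s in scenario.sources])
    for group, props in scenario.true_proportions.items():
        p = np.asarray(props, dtype=float)
        level = scenario.level_of(group)
        base13 = float(p @ mu13) + scenario.tef.d13c
        base15 = float(p @ mu15) + scenario.tef.d15n(level)
        for i in range(scenario.n_per_group):
            rows.append(
                {
                    "group": group,
                    "taxon": group,
                    "specimen_id": f"{group}-{i + 1}",
                    "d13C": base13 + scenario.noise_sd[0] * rng.standard_normal(),
                    "d15N": base15 + scenario.noise_sd[1] * rng.standard_normal(),
                    "role": "consumer",
                }
            )
    return pd.DataFrame(rows)


def two_region_scenario(
    group: str = "plankton",
    n_estuary_sites: int = 3,
    n_bay_sites: int = 6,
    n_seasons: int = 6,
    taxa_per_cluster: int = 12,
    separation: float = 1.0,
    turnover: float | None = None,
    detection_prob: float = 0.9,
    abundance_sigma: float = 0.5,
    site_names: list[str] | None = None,
    seed: int = 0,
) -> CommunityScenario:
    """Estuary-vs-deep-bay survey design with disjoint cluster taxa pools.

    Mirrors the study layout: 9 sites x 6 seasons for plankton/benthos and
    3 x 6 for nekton (``n_estuary_sites=1, n_bay_sites=2``).  Plankton pools
    turn over seasonally by default; benthos and nekton are seasonally stable.
    ``separation`` scales the log-abundance contrast between a cluster's own
    taxa and zero abundance elsewhere (pools are disjoint, so any positive
    abundance separates the regions).  ``site_names`` (first
    ``n_estuary_sites`` estuarine) lets a group sample a subset of the same
    physical stations, as trawled nekton surveys do.
    """
    if turnover is None:
        turnover = 0.33 if group == "plankton" else 0.0
    if site_names is None:
        site_names = [f"st{i + 1}" for i in range(n_estuary_sites + n_bay_sites)]
    if len(site_names) != n_estuary_sites + n_bay_sites:
        raise ValueError("site_names does not match the site counts")
    sites = {name: ("estuary" if i < n_estuary_sites else "bay")
             for i, name in enumerate(site_names)}
    pools = {
        "estuary": tuple(f"{group}_est_{j + 1}" for j in range(taxa_per_cluster)),
        "bay": tuple(f"{group}_bay_{j + 1}" for j in range(taxa_per_cluster)),
    }
    return CommunityScenario(
        site_clusters=sites,
        taxa_pools=pools,
        n_seasons=n_seasons,
        abundance_mean=2.0 * separation,
        abundance_sigma=abundance_sigma,
        detection_prob=detection_prob,
        turnover=turnover,
        seed=seed,
    )
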