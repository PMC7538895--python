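"""End-to-end analysis pipeline: communities -> clusters -> taxa -> food web.

``run_pipeline`` executes the full chain on a declarative configuration:
per-taxonomic-group abundance tables (generated synthetically or loaded from
CSV) are filtered to common taxa, min-max scaled, patterned on a SOM, the
units Ward-clustered and the sample partition tested with MRPP; indicator and
dominant taxa are selected and sympatric clusters associated into
multitrophic communities; isotope mixing models estimate producer
contributions to primary-consumer guilds and benthic dependence / trophic
position of predators; finally the weighted food-web graph is assembled.
Every stage is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterPartition,
    MRPPResult,
    assign_samples,
    kruskal_wallis,
    mrpp,
    pairwise_mann_whitney,
    ward_cluster_units,
)
from .datasets import default_sources
from .foodweb import build_foodweb, export_graph
from .indicators import associate_clusters, dominance, indval_significance, select_dominants
from .mixing import BaselineSet, MixingSolution, TefSet, isosource, tef_correct, trophic_position, two_source_f
from .som import SOMConfig, filter_common_taxa, minmax_scale, propose_grids, select_grid
from .synthetic import (
    CommunityScenario,
    IsotopeScenario,
    SourceSpec,
    generate_community,
    generate_environment,
    generate_isotopes,
    two_region_scenario,
)

__all__ = ["PipelineError", "PipelineResult", "default_config", "run_pipeline", "export_results"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_config() -> dict:
    """The bundled two-channel synthetic scenario.

    Three taxonomic groups mirror the survey design (9 sites x 6 seasons for
    plankton and benthos, 3 x 6 for nekton); plankton pools turn over
    seasonally, benthos and nekton are stable.  Guild diets over three
    producers per locality and predator benthic dependences are the planted
    ground truth recovered by the mixing stage.
    """
    return {
        "seed": 1,
        "community": {
            "filter_threshold": 0.05,
            "groups": {
                "plankton": {
                    "n_estuary_sites": 3,
                    "n_bay_sites": 6,
                    "taxa_per_cluster": 12,
                    "turnover": 0.33,
                },
                "benthos": {
                    "n_estuary_sites": 3,
                    "n_bay_sites": 6,
                    "taxa_per_cluster": 10,
                    "turnover": 0.0,
                },
                "nekton": {
                    "n_estuary_sites": 1,
                    "n_bay_sites": 2,
                    "taxa_per_cluster": 8,
                    "turnover": 0.0,
                    # nekton is trawled at a subset of the same stations
                    "site_names": ["st2", "st5", "st7"],
                },
            },
        },
        "environment": {
            "variables": {
                "salinity": {"estuary": 18.0, "bay": 31.0},
                "spm": {"estuary": 4.0, "bay": 12.6},
            },
            "dispersion": 1.0,
        },
        "som": {
            "grid": "auto",
            "max_candidates": 2,
            "ordering_epochs": 60,
            "tuning_epochs": 200,
        },
        "clustering": {"k": 2, "mrpp_permutations": 199},
        "selection": {"indval_permutations": 199},
        "isotopes": {
            "increment": 0.01,
            "tolerance": 0.1,
            "max_tolerance": 0.5,
            "noise_sd": [0.2, 0.2],
            # a guild pools specimens of several dominant taxa
            "n_per_group": 24,
            "n_per_source": 10,
            "producers": {
                "estuary": ["estuarine_phytoplankton", "microphytobenthos", "Phragmites"],
                "bay": ["deep_bay_phytoplankton", "microphytobenthos", "Zostera"],
            },
            # diets chosen so the benthic/pelagic baseline d13C separation
            # matches the surveyed one (~2.5 permil estuary, ~2.9 permil bay)
            "guild_diets": {
                "estuary": {
                    "suspension_feeders": [0.81, 0.04, 0.15],
                    "deposit_feeders": [0.45, 0.40, 0.15],
                    "zooplankton": [0.80, 0.02, 0.18],
                },
                "bay": {
                    "deposit_feeders": [0.45, 0.40, 0.15],
                    "zooplankton": [0.95, 0.05, 0.00],
                },
            },
            "predators": {
                "estuary": {
                    "predator_est_1": {"f": 0.58, "tp": 3.2},
                    "predator_est_2": {"f": 0.38, "tp": 2.9},
                },
                "bay": {
                    "predator_bay_1": {"f": 0.96, "tp": 2.8},
                    "predator_bay_2": {"f": 0.79, "tp": 3.5},
                    "predator_bay_3": {"f": 0.18, "tp": 3.5},
                },
            },
        },
    }


@dataclass
class PipelineResult:
    config: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    planted_labels: dict[str, pd.Series] = field(default_factory=dict)
    soms: dict = field(default_factory=dict)
    grid_reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    partitions: dict[str, ClusterPartition] = field(default_factory=dict)
    mrpp_results: dict[str, MRPPResult] = field(default_factory=dict)
    environment: pd.DataFrame | None = None
    environment_tests: pd.DataFrame | None = None
    indval_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    dominance_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    dominant_taxa: dict[str, dict] = field(default_factory=dict)
    associations: pd.DataFrame | None = None
    isotope_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    baselines: dict[str, BaselineSet] = field(default_factory=dict)
    mixing_solutions: dict[tuple[str, str], MixingSolution] = field(default_factory=dict)
    trophic_estimates: pd.DataFrame | None = None
    graph: object = None
    truth: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _flatten(config: dict, prefix: str = "") -> dict:
    out = {}
    for key, val in config.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            out.update(_flatten(val, f"{name}."))
        else:
            out[name] = val
    return out


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return json.loads(json.dumps(config))  # deep copy, keep caller's dict intact


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-tagged diagnostics
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("community")
def _community_stage(result: PipelineResult, cfg: dict, seeds: list[int]) -> None:
    comm = cfg["community"]
    if "files" in comm:
        for group, path in comm["files"].items():
            table = pd.read_csv(path, index_col=[0, 1])
            result.tables[group] = table
    else:
        for i, (group, params) in enumerate(sorted(comm["groups"].items())):
            scenario = two_region_scenario(group=group, seed=seeds[i], **params)
            table, planted = generate_community(scenario)
            result.tables[group] = table
            result.planted_labels[group] = planted
    threshold = comm.get("filter_threshold", 0.05)
    for group in list(result.tables):
        result.tables[group] = filter_common_taxa(result.tables[group], threshold)


@_stage("som")
def _som_stage(result: PipelineResult, cfg: dict) -> None:
    som_cfg = cfg["som"]
    for group, table in result.tables.items():
        scaled = minmax_scale(table)
        base = SOMConfig(
            ordering_epochs=som_cfg.get("ordering_epochs", 100),
            tuning_epochs=som_cfg.get("tuning_epochs", 400),
            seed=cfg["seed"],
        )
        if som_cfg.get("grid", "auto") == "auto":
            cands = propose_grids(len(scaled))[: som_cfg.get("max_candidates", 2)]
        else:
            cands = [tuple(som_cfg["grid"])]
        som, report = select_grid(scaled.to_numpy(), cands, base)
        result.soms[group] = (som, scaled)
        result.grid_reports[group] = report


@_stage("clustering")
def _clustering_stage(result: PipelineResult, cfg: dict, seeds: list[int]) -> None:
    k = cfg["clustering"].get("k", 2)
    n_perm = cfg["clustering"].get("mrpp_permutations", 199)
    for i, group in enumerate(sorted(result.soms)):
        som, scaled = result.soms[group]
        partition = ward_cluster_units(som, k)
        labels = assign_samples(som, scaled, partition)
        result.partitions[group] = partition
        counts = labels.value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            result.mrpp_results[group] = mrpp(
                scaled.to_numpy(), labels.to_numpy(), n_perm=n_perm, seed=seeds[i]
            )


@_stage("environment")
def _environment_stage(result: PipelineResult, cfg: dict, seed: int) -> None:
    env_cfg = cfg.get("environment")
    if not env_cfg or "plankton" not in result.partitions:
        return
    labels = result.partitions["plankton"].sample_labels
    planted = result.planted_labels.get("plankton")
    if planted is not None:
        # name recovered clusters after the planted cluster they mostly contain
        mapping = {
            c: planted.loc[labels.index][labels == c].mode().iloc[0]
            for c in labels.unique()
        }
        labels = labels.map(mapping)
    medians = pd.DataFrame(env_cfg["variables"]).T
    env = generate_environment(labels, medians, env_cfg.get("dispersion", 0.0), seed)
    result.environment = env
    rows = []
    for var in env.columns:
        h, p = kruskal_wallis(env[var], labels)
        rows.append({"variable": var, "H": h, "p": p})
    result.environment_tests = pd.DataFrame(rows)


@_stage("selection")
def _selection_stage(result: PipelineResult, cfg: dict, seeds: list[int]) -> None:
    n_perm = cfg["selection"].get("indval_permutations", 199)
    for i, group in enumerate(sorted(result.tables)):
        table = result.tables[group]
        labels = result.partitions[group].sample_labels
        result.indval_tables[group] = indval_significance(
            table, labels, n_perm=n_perm, seed=seeds[i]
        )
        records = select_dominants(dominance(table, labels))
        result.dominance_tables[group] = records
        dom = records[records["dominant"]]
        result.dominant_taxa[group] = {
            cluster: tuple(sub["taxon"]) for cluster, sub in dom.groupby("cluster")
        }


@_stage("association")
def _association_stage(result: PipelineResult) -> None:
    partitions = {g: p.sample_labels for g, p in result.partitions.items()}
    result.associations = associate_clusters(partitions, result.dominant_taxa)


@_stage("mixing")
def _mixing_stage(result: PipelineResult, cfg: dict, seeds: list[int]) -> None:
    iso = cfg["isotopes"]
    tef = TefSet()
    source_by_name = {s.name: s for s in default_sources()}
    increment, tolerance = iso.get("increment", 0.01), iso.get("tolerance", 0.1)
    max_tol = iso.get("max_tolerance", 0.5)
    noise = tuple(iso.get("noise_sd", (0.3, 0.3)))

    truth_edges = {}
    estimates = []
    for li, (locality, diets) in enumerate(sorted(iso["guild_diets"].items())):
        producer_names = iso["producers"][locality]
        sources = tuple(source_by_name[n] for n in producer_names)
        scenario = IsotopeScenario(
            sources=sources,
            true_proportions={g: tuple(p) for g, p in diets.items()},
            tef=tef,
            consumer_level="primary",
            noise_sd=noise,
            n_per_group=iso.get("n_per_group", 8),
            n_per_source=iso.get("n_per_source", 10),
            seed=seeds[li],
        )
        iso_table = generate_isotopes(scenario)
        for guild, props in diets.items():
            truth_edges[(locality, guild)] = pd.Series(
                list(props), index=list(producer_names)
            )

        consumers = iso_table[iso_table["role"] == "consumer"]
        guild_means = consumers.groupby("group")[["d13C", "d15N"]].mean()
        base = BaselineSet(
            pelagic_d13c=float(guild_means.loc["zooplankton", "d13C"]),
            pelagic_d15n=float(guild_means.loc["zooplankton", "d15N"]),
            benthic_d13c=float(guild_means.loc["deposit_feeders", "d13C"]),
            benthic_d15n=float(guild_means.loc["deposit_feeders", "d15N"]),
        )
        result.baselines[locality] = base

        # predator specimens: planted f on the local benthic-pelagic axis
        rng = np.random.default_rng(seeds[len(iso["guild_diets"]) + li])
        pred_rows = []
        for taxon, spec in sorted(iso["predators"].get(locality, {}).items()):
            f_true, tp_true = spec["f"], spec["tp"]
            mu13 = (
                base.pelagic_d13c
                + f_true * (base.benthic_d13c - base.pelagic_d13c)
                + tef.d13c
            )
            base15 = base.benthic_d15n * f_true + base.pelagic_d15n * (1 - f_true)
            mu15 = base15 + tef.d15n_carnivore * (tp_true - base.lambda_baseline)
            for i in range(iso.get("n_per_group", 8)):
                pred_rows.append(
                    {
                        "group": taxon,
                        "taxon": taxon,
                        "specimen_id": f"{taxon}-{i + 1}",
                        "d13C": mu13 + noise[0] * rng.standard_normal(),
                        "d15N": mu15 + noise[1] * rng.standard_normal(),
                        "role": "consumer",
                    }
                )
        iso_table = pd.concat([iso_table, pd.DataFrame(pred_rows)], ignore_index=True)
        result.isotope_tables[locality] = iso_table

        # invert guild diets with the IsoSource enumeration
        source_table = pd.DataFrame(
            {
                "d13C": [s.d13c_mean for s in sources],
                "d15N": [s.d15n_mean for s in sources],
            },
            index=pd.Index(producer_names, name="source"),
        )
        for guild in diets:
            mean13 = float(guild_means.loc[guild, "d13C"])
            mean15 = float(guild_means.loc[guild, "d15N"])
            mixture = tef_correct(mean13, mean15, tef, level="primary")
            tol = tolerance
            sol = isosource(mixture, source_table, increment=increment, tolerance=tol)
            while sol.is_empty and tol * 2 <= max_tol:
                tol *= 2
                warnings.warn(
                    f"no feasible mixture for {locality}/{guild}; "
                    f"tolerance widened to {tol} permil",
                    stacklevel=2,
                )
                sol = isosource(mixture, source_table, increment=increment, tolerance=tol)
            if sol.is_empty:
                raise ValueError(
                    f"{locality}/{guild}: consumer outside the source polygon "
                    f"by {sol.polygon_distance:.2f} permil"
                )
            result.mixing_solutions[(locality, guild)] = sol

        # predator benthic dependence and trophic position
        pred_table = pd.DataFrame(pred_rows)
        if len(pred_table):
            means = pred_table.groupby("taxon")[["d13C", "d15N"]].mean()
            for taxon in means.index:
                f, f_raw = two_source_f(float(means.loc[taxon, "d13C"]), base, tef.d13c)
                est = trophic_position(
                    float(means.loc[taxon, "d15N"]),
                    f,
                    base,
                    tef_d15n=tef.d15n_carnivore,
                    taxon=taxon,
                    locality=locality,
                    f_raw=f_raw,
                )
                estimates.append(
                    {
                        "taxon": est.taxon,
                        "locality": est.locality,
                        "f_raw": est.f_raw,
                        "f": est.f,
                        "d15n_baseline": est.d15n_baseline,
                        "tp": est.tp,
                    }
                )

    result.trophic_estimates = pd.DataFrame(estimates)
    result.truth["guild_diets"] = truth_edges
    result.truth["predators"] = {
        (loc, taxon): spec
        for loc, preds in iso["predators"].items()
        for taxon, spec in preds.items()
    }


@_stage("foodweb")
def _foodweb_stage(result: PipelineResult) -> None:
    contributions = {
        key: sol.medians for key, sol in result.mixing_solutions.items()
    }
    result.graph = build_foodweb(contributions, result.trophic_estimates)


def run_pipeline(config=None) -> PipelineResult:
    """Run the full analysis; fully reproducible from the config and its seed."""
    cfg = _load_config(config) if config is not None else default_config()
    if "seed" not in cfg:
        raise PipelineError("config", "a seed is mandatory")
    result = PipelineResult(config=cfg)
    n_groups = len(cfg["community"].get("groups", {})) or 3
    seeds = _child_seeds(cfg["seed"], 4 * n_groups + 8)

    _community_stage(result, cfg, seeds[:n_groups])
    _som_stage(result, cfg)
    _clustering_stage(result, cfg, seeds[n_groups : 2 * n_groups])
    _environment_stage(result, cfg, seeds[2 * n_groups])
    _selection_stage(result, cfg, seeds[2 * n_groups + 1 : 3 * n_groups + 1])
    _association_stage(result)
    _mixing_stage(result, cfg, seeds[3 * n_groups + 1 :])
    _foodweb_stage(result)

    result.manifest = {
        "package": "baywebs",
        "version": __version__,
        "config": _flatten(cfg),
    }
    return result


def export_results(result: PipelineResult, out_dir) -> list[Path]:
    """Write every stage's outputs plus a run manifest; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(frame: pd.DataFrame, name: str, **kwargs):
        path = out / name
        frame.to_csv(path, **kwargs)
        written.append(path)

    for group, table in result.tables.items():
        save(table, f"abundance_{group}.csv")
    for group, part in result.partitions.items():
        save(part.sample_labels.to_frame(), f"clusters_{group}.csv")
    if result.mrpp_results:
        save(
            pd.DataFrame(
                [
                    {"group": g, "A": r.A, "delta": r.delta_observed, "p": r.p}
                    for g, r in result.mrpp_results.items()
                ]
            ),
            "mrpp.csv",
            index=False,
        )
    for group, table in result.indval_tables.items():
        save(table, f"indval_{group}.csv", index=False)
    for group, table in result.dominance_tables.items():
        save(table, f"dominance_{group}.csv", index=False)
    if result.associations is not None:
        save(result.associations, "associations.csv")
    if result.environment is not None:
        save(result.environment, "environment.csv")
    for locality, table in result.isotope_tables.items():
        save(table, f"isotopes_{locality}.csv", index=False)
    if result.mixing_solutions:
        save(
            pd.concat(
                {
                    f"{loc}/{guild}": sol.summary()
                    for (loc, guild), sol in result.mixing_solutions.items()
                },
                names=["consumer"],
            ),
            "mixing_contributions.csv",
        )
    if result.trophic_estimates is not None:
        save(result.trophic_estimates, "trophic_estimates.csv", index=False)
    if result.graph is not None:
        export_graph(result.graph, out / "foodweb_edges.csv", out / "foodweb.graphml")
        written += [out / "foodweb_edges.csv", out / "foodweb.graphml"]
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    written.append(manifest_path)
    return written
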