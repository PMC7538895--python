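"""Weighted benthic/pelagic food-web graphs from mixing-model output.

Nodes are producers, primary-consumer guilds (suspension feeders, deposit
feeders, zooplankton) and predator taxa, each tied to a locality.  Directed
prey -> consumer edges carry the relative contribution of the prey to the
consumer's nutrition: producer -> guild edges take the renormalized feasible
medians of the mixing model, guild -> predator edges split f : (1 - f)
between the benthic and pelagic baseline guilds.  Incoming weights into every
consumer sum to 1.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_foodweb", "export_graph", "read_edge_list"]

DEFAULT_SOURCE_PATHWAYS = {
    "riverine_SPOM": "pelagic",
    "estuarine_phytoplankton": "pelagic",
    "deep_bay_phytoplankton": "pelagic",
    "Phragmites": "benthic",
    "microphytobenthos": "benthic",
    "Zostera": "benthic",
}


def _node(locality: str, name: str) -> str:
    return f"{locality}:{name}"


def build_foodweb(
    producer_contributions: dict[tuple[str, str], pd.Series],
    trophic_estimates: pd.DataFrame | None = None,
    source_pathways: dict[str, str] | None = None,
    benthic_guild: str = "deposit_feeders",
    pelagic_guild: str = "zooplankton",
) -> nx.DiGraph:
    """Assemble the weighted trophic network.

    Parameters
    ----------
    producer_contributions : {(locality, guild): medians} — feasible-median
        contribution of each producer to the guild's nutrition; renormalized
        to sum to 1.
    trophic_estimates : rows (taxon, locality, f, tp); predators with a
        missing f keep their node but get no edges (with a warning).
    source_pathways : producer name -> 'pelagic' | 'benthic'; unknown
        producers default to 'pelagic'.
    """
    pathways = {**DEFAULT_SOURCE_PATHWAYS, **(source_pathways or {})}
    g = nx.DiGraph()

    for (locality, guild), medians in producer_contributions.items():
        medians = pd.Series(medians).astype(float)
        total = medians.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError(f"invalid contributions for {(locality, guild)}")
        weights = medians / total
        guild_node = _node(locality, guild)
        g.add_node(guild_node, role="primary_consumer", locality=locality, guild=guild)
        for producer, w in weights.items():
            prod_node = _node(locality, str(producer))
            g.add_node(prod_node, role="producer", locality=locality)
            g.add_edge(
                prod_node,
                guild_node,
                weight=float(w),
                pathway=pathways.get(str(producer), "pelagic"),
            )

    if trophic_estimates is not None and len(trophic_estimates):
        for _, row in trophic_estimates.iterrows():
            locality = row["locality"]
            pred = _node(locality, row["taxon"])
            g.add_node(
                pred,
                role="predator",
                locality=locality,
                tp=float(row["tp"]) if np.isfinite(row.get("tp", np.nan)) else None,
            )
            f = row.get("f", np.nan)
            if not np.isfinite(f):
                warnings.warn(
                    f"predator {row['taxon']!r} lacks an f estimate; edges omitted",
                    stacklevel=2,
                )
                continue
            for guild, weight, pathway in (
                (benthic_guild, float(f), "benthic"),
                (pelagic_guild, 1.0 - float(f), "pelagic"),
            ):
                guild_node = _node(locality, guild)
                if guild_node not in g:
                    g.add_node(
                        guild_node,
                        role="primary_consumer",
                        locality=locality,
                        guild=guild,
                    )
                if weight > 0:
                    g.add_edge(guild_node, pred, weight=weight, pathway=pathway)
    return g


def edge_table(g: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "source": u,
            "target": v,
            "weight": d.get("weight", np.nan),
            "pathway": d.get("pathway", ""),
        }
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "pathway"])


def export_graph(g: nx.DiGraph, edge_csv, graphml_path=None) -> None:
    """Write the canonical edge-list CSV, plus GraphML for graph tools."""
    edge_table(g).to_csv(edge_csv, index=False)
    if graphml_path is not None:
        h = g.copy()
        for _, data in h.nodes(data=True):
            for k in list(data):
                if data[k] is None:
                    del data[k]
        nx.write_graphml(h, graphml_path)


def read_edge_list(edge_csv) -> nx.DiGraph:
    """Rebuild a graph from an exported edge-list CSV (round-trip inverse)."""
    table = pd.read_csv(edge_csv)
    g = nx.DiGraph()
    for _, row in table.iterrows():
        g.add_edge(
            row["source"],
            row["target"],
            weight=float(row["weight"]),
            pathway=row["pathway"] if isinstance(row["pathway"], str) else "",
        )
    return g
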