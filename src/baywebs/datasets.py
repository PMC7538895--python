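"""Published reference inputs for the Gwangyang Bay survey.

Small published summary tables, bundled so the worked examples and the
reproduction script run without external downloads: isotopic baselines of
the pelagic (zooplankton) and benthic (deposit feeder) pathways in the
estuarine channel and the deep bay, trophic enrichment factors, and the
mean d13C/d15N signatures of the dominant predatory consumers.
"""

from __future__ import annotations

import pandas as pd

from .mixing import BaselineSet, TefSet
from .synthetic import SourceSpec

__all__ = [
    "TEFS",
    "DEEP_BAY_BASELINES",
    "ESTUARINE_BASELINES",
    "baseline_endmembers",
    "deep_bay_predator_means",
    "estuarine_predator_means",
    "default_sources",
]

TEFS = TefSet()

# area-pooled mean baselines (permil): pelagic = zooplankton, benthic = deposit feeders
DEEP_BAY_BASELINES = BaselineSet(
    pelagic_d13c=-19.5, pelagic_d15n=9.5, benthic_d13c=-16.7, benthic_d15n=10.5
)
ESTUARINE_BASELINES = BaselineSet(
    pelagic_d13c=-23.8, pelagic_d15n=9.5, benthic_d13c=-21.3, benthic_d15n=11.4
)


def baseline_endmembers() -> pd.DataFrame:
    """The four baseline end-members used for motile estuarine consumers."""
    return pd.DataFrame(
        {
            "d13C": [-21.3, -23.8, -16.7, -19.5],
            "d15N": [11.4, 9.5, 10.5, 9.5],
        },
        index=pd.Index(
            [
                "estuary_benthic",
                "estuary_pelagic",
                "deep_bay_benthic",
                "deep_bay_pelagic",
            ],
            name="endmember",
        ),
    )


# (taxon, group, mean d13C, mean d15N) of dominant deep-bay predators
_DEEP_BAY_PREDATORS = [
    ("Glycera chirori", "macrobenthos", -15.9, 13.6),
    ("Sigambra tentaculata", "macrobenthos", -16.1, 13.2),
    ("Scoletoma longifolia", "macrobenthos", -16.1, 12.9),
    ("Charybdis bimaculata", "crustacean", -15.7, 12.0),
    ("Oratosquilla oratoria", "crustacean", -15.5, 13.2),
    ("Parapenaeopsis tenella", "crustacean", -16.0, 12.0),
    ("Metapenaeus joyneri", "crustacean", -16.0, 11.9),
    ("Trachysalambria curvirostris", "crustacean", -14.4, 12.6),
    ("Portunus trituberculatus", "crustacean", -15.0, 12.8),
    ("Palaemon gravieri", "crustacean", -14.4, 13.5),
    ("Alpheus japonicus", "crustacean", -14.2, 12.9),
    ("Alpheus digitalis", "crustacean", -14.1, 12.6),
    ("Loligo japonica", "cephalopod", -15.8, 14.3),
    ("Octopus variabilis", "cephalopod", -15.5, 13.6),
    ("Euprymna morsei", "cephalopod", -14.7, 13.0),
    ("Pleuronectes yokohamae", "fish", -16.0, 15.4),
    ("Leiognathus nuchalis", "fish", -16.2, 15.0),
    ("Cynoglossus joyneri", "fish", -15.0, 13.6),
    ("Amblychaeturichthys hexanema", "fish", -15.1, 14.2),
    ("Pennahia argentata", "fish", -15.2, 14.9),
    ("Thryssa kammalensis", "fish", -17.7, 14.6),
    ("Okamejei kenojei", "fish", -14.4, 13.4),
    ("Ctenotrypauchen microcephalus", "fish", -15.7, 14.1),
    ("Johnius grypotus", "fish", -14.7, 14.4),
]

# motile consumers sampled in the estuarine channel (outside the local
# two-source axis; handled with the four-end-member mixing model)
_ESTUARINE_PREDATORS = [
    ("Charybdis japonica", "crustacean", -17.2, 13.9),
    ("Crangon hakodatei", "crustacean", -17.4, 12.9),
    ("Trachysalambria curvirostris", "crustacean", -17.3, 13.2),
    ("Leiognathus nuchalis", "fish", -18.5, 14.7),
    ("Konosirus punctatus", "fish", -16.1, 13.3),
]


def _predator_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["taxon", "group", "d13C", "d15N"]).set_index(
        "taxon"
    )


def deep_bay_predator_means() -> pd.DataFrame:
    """Mean isotope signatures of the dominant deep-bay predatory consumers."""
    return _predator_frame(_DEEP_BAY_PREDATORS)


def estuarine_predator_means() -> pd.DataFrame:
    """Mean signatures of the motile estuarine-channel predators."""
    return _predator_frame(_ESTUARINE_PREDATORS)


def default_sources() -> tuple[SourceSpec, ...]:
    """Organic-matter source signatures for the synthetic scenarios.

    Phytoplankton means/SDs are the cluster-pooled survey values; the wetland
    producers are realistic synthetic stand-ins anchored to the reported
    extremes of the producer ranges (-27.5 +/- 0.6 to -8.6 +/- 1.0 permil
    d13C; 5.4 +/- 0.4 to 8.5 +/- 0.8 permil d15N).
    """
    return (
        SourceSpec("riverine_SPOM", -27.5, 0.6, 5.4, 0.4),
        SourceSpec("Phragmites", -25.5, 0.5, 6.0, 0.5),
        SourceSpec("estuarine_phytoplankton", -22.9, 2.6, 7.8, 2.1),
        SourceSpec("deep_bay_phytoplankton", -19.9, 1.8, 7.8, 2.1),
        SourceSpec("microphytobenthos", -16.5, 0.8, 7.0, 0.6),
        SourceSpec("Zostera", -8.6, 1.0, 8.5, 0.8),
    )
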