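import numpy as np
import pandas as pd
import pytest

from baywebs import (
    CommunityScenario,
    SOMConfig,
    filter_common_taxa,
    generate_community,
    minmax_scale,
    train_som,
)


@pytest.fixture
def two_cluster_scenario():
    """Disjoint estuary/bay taxa pools, no noise knobs turned up."""
    sites = {f"st{i}": ("estuary" if i <= 3 else "bay") for i in range(1, 10)}
    pools = {
        "estuary": tuple(f"est_{j}" for j in range(1, 9)),
        "bay": tuple(f"bay_{j}" for j in range(1, 9)),
    }
    return CommunityScenario(
        site_clusters=sites,
        taxa_pools=pools,
        n_seasons=4,
        abundance_mean=2.0,
        abundance_sigma=0.4,
        detection_prob=0.95,
        turnover=0.0,
        seed=7,
    )


@pytest.fixture
def planted_table(two_cluster_scenario):
    table, planted = generate_community(two_cluster_scenario)
    return table, planted


@pytest.fixture
def trained_planted_som(planted_table):
    table, planted = planted_table
    scaled = minmax_scale(filter_common_taxa(table))
    cfg = SOMConfig(grid=(4, 4), ordering_epochs=40, tuning_epochs=120, seed=0)
    som = train_som(scaled.to_numpy(), cfg)
    return som, scaled, planted
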