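import numpy as np
import pandas as pd
import pytest

from drpredict import DR, NOT_DR, LabeledGeneSet, SimulationConfig
from drpredict.synthetic_data import simulate_labels


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=60,
        minority_fraction=0.2,
        n_binary_features=30,
        n_enriched_features=4,
        enrichment_odds=6.0,
        base_positive_rate=0.1,
        n_continuous_features=10,
        continuous_effect_size=1.5,
        dag_depth=3,
        dag_branching=2,
        graph_n_nodes=20,
        graph_edge_density=0.15,
        seed=7,
    )


@pytest.fixture
def small_labels(small_config) -> LabeledGeneSet:
    return simulate_labels(small_config)


@pytest.fixture
def toy_labels() -> LabeledGeneSet:
    return LabeledGeneSet.from_arrays(
        ["g1", "g2", "g3", "g4", "g5", "g6"],
        [DR, DR, NOT_DR, NOT_DR, NOT_DR, NOT_DR],
    )


def make_labels(n_minority: int, n_majority: int, prefix: str = "g") -> LabeledGeneSet:
    ids = [f"{prefix}{i:04d}" for i in range(n_minority + n_majority)]
    labels = [DR] * n_minority + [NOT_DR] * n_majority
    return LabeledGeneSet.from_arrays(ids, labels)
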