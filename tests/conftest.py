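import numpy as np
import pandas as pd
import pytest

from microscape import gating, synth


@pytest.fixture(scope="session")
def tissue():
    """A seeded 5000-cell demonstration tissue shared across tests."""
    config = synth.default_tissue_config(n_cells=5000, seed=11)
    table, truth = synth.generate_tissue(config)
    return config, table, truth


@pytest.fixture(scope="session")
def gated_tissue(tissue):
    config, table, truth = tissue
    scaled = gating.scale_table(table, truth.gates)
    flags = gating.positivity_frame(scaled)
    labels = gating.classify_cells(flags, gating.default_rule_tree())
    scaled = scaled.copy()
    scaled["phenotype"] = labels
    return config, scaled, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simple_gates():
    return gating.GateConfig.from_dict(
        {"M1": {"low": 100.0, "gate": 500.0, "high": 2000.0}}
    )


@pytest.fixture
def small_cell_csv(tmp_path):
    path = tmp_path / "cells.csv"
    pd.DataFrame(
        {
            "cell_id": ["a", "b", "c"],
            "x": [0.0, 10.0, 20.0],
            "y": [0.0, 5.0, 15.0],
            "CD45": [10.0, 900.0, 15.0],
        }
    ).to_csv(path, index=False)
    return path
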