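"""Shared fixtures: small synthetic bundles and on-disk artifacts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flabkit import PresenceMatrix, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 40 strains, 300 families, 6 focal in 2 clades."""
    return SimulationConfig(
        seed=11,
        n_strains=40,
        n_families=300,
        n_focal=6,
        n_focal_clades=2,
        n_planted_missing=5,
        n_planted_specific=1,
        n_padding=150,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def toy_presence() -> PresenceMatrix:
    """Hand-sized matrix: 4 families x 5 strains."""
    df = pd.DataFrame(
        {
            "A": [1, 0, 1, 1],
            "B": [1, 0, 1, 0],
            "C": [0, 1, 1, 0],
            "D": [0, 1, 1, 1],
            "E": [1, 1, 1, 0],
        },
        index=pd.Index(["K1", "K2", "K3", "K4"], name="family_id"),
    )
    return PresenceMatrix(df)


def random_presence(rng: np.random.Generator, n_strains: int, n_families: int) -> PresenceMatrix:
    """Random binary matrix helper used by oracle-equivalence tests."""
    vals = rng.integers(0, 2, size=(n_families, n_strains))
    # guarantee no all-identical degenerate matrix
    vals[0, 0] = 1
    df = pd.DataFrame(
        vals,
        index=pd.Index([f"K{i:03d}" for i in range(n_families)], name="family_id"),
        columns=[f"S{j + 1}" for j in range(n_strains)],
    )
    return PresenceMatrix(df)
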