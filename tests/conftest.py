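"""Shared fixtures: tiny deterministic synthetic data and trained models."""

from __future__ import annotations

import numpy as np
import pytest

from valvesynth import representation as rep
from valvesynth import synthetic as syn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Ten strongly coupled synthetic valves."""
    return syn.sample_dataset(10, "strong", seed=7)


@pytest.fixture(scope="session")
def leaflet_stack(small_dataset):
    return np.stack([r.leaflets[lt].pixels for r in small_dataset
                     for lt in ("rc", "lc", "nc")])


@pytest.fixture(scope="session")
def volume_stack(small_dataset):
    return np.stack([r.volume.voxels for r in small_dataset])


@pytest.fixture(scope="session")
def tiny_leaflet_ae(leaflet_stack):
    """A briefly but adequately trained leaflet autoencoder (shared)."""
    model = rep.build_autoencoder(rep.OPTIMAL_LEAFLET_SPEC, seed=0)
    rep.train_autoencoder(model, leaflet_stack,
                          rep.TrainConfig(epochs=20, batch_size=8, seed=0))
    return model
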