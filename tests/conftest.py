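"""Shared fixtures: small synthetic cohorts and a quickly overfit model."""

from __future__ import annotations

import numpy as np
import pytest

from msanet.experiments import (
    build_training_items,
    default_genotype_configs,
    simulate_cohort,
)
from msanet.model import ModelConfig, MSANet, TrainConfig, train


@pytest.fixture(scope="session")
def small_cohort():
    """Six 64x64 plants across the two default genotypes."""
    cfgs = default_genotype_configs(seed=11, image_size=(64, 64))
    return simulate_cohort(cfgs, n_plants=3)


@pytest.fixture(scope="session")
def overfit_model(small_cohort):
    """A tiny model overfit on the small cohort; good enough for readout tests."""
    model = MSANet(ModelConfig(backbone="tiny_cnn", rng_seed=3))
    items = build_training_items(small_cohort)
    train(model, items, TrainConfig(steps=400, lr=3e-3, shuffle_seed=3))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
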