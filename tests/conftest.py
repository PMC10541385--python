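"""Shared fixtures: a trained curve-correction model and common phantoms.

The trained model is session-scoped because training (1152 pairs,
50 epochs) takes tens of seconds; every test that needs inference shares
the same deterministic model.
"""

import numpy as np
import pytest

import ctperf as c
from ctperf.training import training_bank

TRAIN_SEED = 0
TRAIN_EPOCHS = 50
N_DATASETS = 128  # x 3 AIFs = 384 source curves -> 1152 augmented pairs


@pytest.fixture(scope="session")
def training_pairs():
    return training_bank(n_datasets=N_DATASETS, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_model(training_pairs):
    model = c.build_model(c.CNNConfig(epochs=TRAIN_EPOCHS, seed=TRAIN_SEED))
    c.train_model(model, training_pairs)
    return model


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, undistorted default phantom."""
    import dataclasses

    cfg = dataclasses.replace(c.PhantomConfig(), noise_snr=None)
    study, truth = c.generate_phantom(cfg, seed=11)
    return cfg, study, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom (SNR 10), clean AIF in the artery."""
    cfg = c.PhantomConfig()
    study, truth = c.generate_phantom(cfg, seed=7)
    return cfg, study, truth
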