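"""Shared fixtures: seeded synthetic data and one trained desk-scale model.

The desk-scale autoencoder (64 px patches, 8->16->32 channels, 128-dim
latent, 30 epochs on 500 synthetic normal patches) is trained once per
session and reused by every test that needs a trained scoring model.
"""

import numpy as np
import pytest
from hypothesis import settings

from plaqrisk import anomaly, synthetic

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

DESK_SPEC = anomaly.AutoencoderSpec(input_px=64, channels=(8, 16, 32), latent_dim=128)
DESK_CFG = anomaly.TrainConfig(epochs=30, batch_size=64, learning_rate=1e-3,
                               optimizer="adam", early_stop_patience=30, seed=1)


@pytest.fixture(scope="session")
def train_bank():
    """500 normal 64-px patches used to train the desk autoencoder."""
    return synthetic.generate_patch_bank(
        synthetic.SlideGenConfig(seed=7), 500, 0, patch_px=64)


@pytest.fixture(scope="session")
def desk_autoencoder(train_bank):
    model, losses = anomaly.train_autoencoder(train_bank, DESK_SPEC, DESK_CFG)
    return model, losses


@pytest.fixture(scope="session")
def heldout_bank():
    """Held-out 100 normal + 100 anomalous patches (disjoint seed)."""
    return synthetic.generate_patch_bank(
        synthetic.SlideGenConfig(seed=99), 100, 100, patch_px=64)


def patient_banks(n_normal: int, n_abnormal: int, patches_per_patient: int = 20,
                  anomalous_per_abnormal: int = 6, base_seed: int = 500):
    """Per-patient patch banks: abnormal patients carry some lesion patches."""
    banks = {}
    labels = {}
    for i in range(n_normal + n_abnormal):
        abnormal = i >= n_normal
        n_anom = anomalous_per_abnormal if abnormal else 0
        cfg = synthetic.SlideGenConfig(seed=base_seed + i)
        bank = synthetic.generate_patch_bank(
            cfg, patches_per_patient - n_anom, n_anom, patch_px=64)
        pid = f"P{i:04d}"
        banks[pid] = bank
        labels[pid] = int(abnormal)
    return banks, labels


@pytest.fixture(scope="session")
def scored_cohort(desk_autoencoder):
    """Risk scores A_p for a 50 normal / 21 abnormal synthetic cohort."""
    model, _ = desk_autoencoder
    banks, labels = patient_banks(50, 21)
    risk = {pid: float(np.mean(anomaly.score_patches(model, bank)))
            for pid, bank in banks.items()}
    return risk, labels
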