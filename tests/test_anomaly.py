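"""Anomaly scores against brute-force loop oracles; training behavior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plaqrisk import anomaly, synthetic
from plaqrisk.anomaly import (AutoencoderSpec, EarlyStopper, FanoganSpec,
                              FanoganTrainConfig, TrainConfig, izif_score,
                              reconstruction_score, select_checkpoint,
                              train_autoencoder, train_fanogan)
from plaqrisk.patching import PatchRecord
from plaqrisk.synthetic import SlideGenConfig


def loop_mse(x, x_hat):
    total, n = 0.0, 0
    for a, b in zip(x.ravel(), x_hat.ravel()):
        total += (float(a) - float(b)) ** 2
        n += 1
    return total / n


class TestScoreFormulas:
    def test_perfect_reconstruction_scores_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, (3, 8, 8))
        assert reconstruction_score(x, x) == 0.0
        assert izif_score(x, x, np.ones(5), np.ones(5)) == 0.0

    def test_unit_residual_scores_one(self):
        x = np.ones((3, 4, 4))
        assert reconstruction_score(x, np.zeros_like(x)) == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=(8, 8, 3))
            y = rng.normal(size=(8, 8, 3))
            expected = loop_mse(x, y)
            got = reconstruction_score(x, y)
            assert abs(got - expected) <= 1e-12 * max(1.0, abs(expected))

    def test_izif_matches_brute_force_sum(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.normal(size=(3, 6, 6)), rng.normal(size=(3, 6, 6))
            fx, fy = rng.normal(size=11), rng.normal(size=11)
            expected = loop_mse(x, y) + loop_mse(fx, fy)
            got = izif_score(x, y, fx, fy)
            assert abs(got - expected) <= 1e-12 * max(1.0, abs(expected))

    def test_izif_reduces_to_mse_when_features_match(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(3, 5, 5)), rng.normal(size=(3, 5, 5))
        f = rng.normal(size=7)
        assert izif_score(x, y, f, f) == pytest.approx(reconstruction_score(x, y))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_score(np.zeros((3, 4, 4)), np.zeros((3, 4, 5)))
        with pytest.raises(ValueError):
            izif_score(np.zeros(4), np.zeros(4), np.zeros(3), np.zeros(2))

    @given(st.integers(0, 100))
    def test_scores_in_unit_range_for_unit_inputs(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, size=(3, 4, 4))
        y = rng.uniform(0, 1, size=(3, 4, 4))
        s = reconstruction_score(x, y)
        assert 0.0 <= s <= 1.0


def _patch(pixels, label="normal"):
    return PatchRecord("p", "s", 0, 0, pixels.shape[0], 1.0,
                       pixels=pixels, label=label)


class TestAutoencoderTraining:
    def test_overfits_identical_patches(self):
        # a smooth color-gradient patch: band-limited like real tissue texture
        yy, xx = np.mgrid[:16, :16] / 15.0
        base = np.stack([150 + 60 * yy, 120 + 40 * xx, 140 + 30 * yy * xx],
                        axis=-1).astype(np.uint8)
        patches = [_patch(base.copy()) for _ in range(10)]
        spec = AutoencoderSpec(input_px=16, channels=(4, 8, 16), latent_dim=32)
        cfg = TrainConfig(epochs=200, batch_size=10, learning_rate=5e-3, seed=0,
                          early_stop_patience=200)
        _, losses = train_autoencoder(patches, spec, cfg)
        assert losses[-1] < 1e-3

    def test_seeded_training_is_reproducible(self):
        bank = synthetic.generate_patch_bank(SlideGenConfig(seed=5), 20, 0, patch_px=32)
        spec = AutoencoderSpec(input_px=32, channels=(4, 8, 16), latent_dim=16)
        cfg = TrainConfig(epochs=5, batch_size=10, seed=3)
        _, la = train_autoencoder(bank, spec, cfg)
        _, lb = train_autoencoder(bank, spec, cfg)
        assert la == lb

    def test_anomalous_patch_in_training_set_rejected(self):
        bank = synthetic.generate_patch_bank(SlideGenConfig(seed=6), 5, 1, patch_px=32)
        spec = AutoencoderSpec(input_px=32, channels=(4, 8, 16), latent_dim=16)
        with pytest.raises(ValueError, match="anomalous"):
            train_autoencoder(bank, spec, TrainConfig(epochs=1, batch_size=4, seed=0))

    def test_trained_model_separates_held_out_classes(self, desk_autoencoder, heldout_bank):
        from sklearn.metrics import roc_auc_score

        model, losses = desk_autoencoder
        assert losses[0] > losses[-1]
        scores = anomaly.score_patches(model, heldout_bank)
        labels = [1 if r.label == "anomalous" else 0 for r in heldout_bank]
        assert roc_auc_score(labels, scores) >= 0.90
        assert np.asarray(scores).min() >= 0.0


class TestFanogan:
    def test_checkpoint_selection_is_argmin(self):
        assert select_checkpoint([40.0, 25.0, 31.0]) == 1
        assert select_checkpoint([2.0, 2.0]) == 0
        with pytest.raises(ValueError):
            select_checkpoint([])

    def test_early_stop_after_flat_patience(self):
        stopper = EarlyStopper(patience=30)
        assert stopper.update(1.0) is False
        stops = [stopper.update(1.0) for _ in range(30)]
        assert stops[:-1] == [False] * 29 and stops[-1] is True

    def test_encoder_before_gan_rejected(self):
        model = anomaly.FanoganModel(
            FanoganSpec(input_px=32, latent_dim=8), np.random.default_rng(0))
        with pytest.raises(RuntimeError):
            anomaly._train_encoder(model, np.zeros((4, 3, 32, 32), np.float32),
                                   FanoganTrainConfig(), np.random.default_rng(0))
        bank = synthetic.generate_patch_bank(SlideGenConfig(seed=1), 1, 0, patch_px=32)
        with pytest.raises(ValueError):
            anomaly.fanogan_score(model, bank[0])

    def test_synthetic_bank_median_ordering(self):
        bank = synthetic.generate_patch_bank(SlideGenConfig(seed=21), 200, 0, patch_px=32)
        spec = FanoganSpec(input_px=32, latent_dim=32,
                           gen_channels=(16, 8), critic_channels=(8, 16))
        cfg = FanoganTrainConfig(gan_epochs=15, encoder_epochs=20, batch_size=64,
                                 checkpoint_every=5, encoder_patience=30, seed=2)
        model, log = train_fanogan(bank, spec, cfg)
        assert log["selected_checkpoint"] == int(np.argmin(log["fid_scores"]))
        test = synthetic.generate_patch_bank(SlideGenConfig(seed=77), 30, 30, patch_px=32)
        scores = anomaly.score_patches(model, test)
        labels = np.array([r.label == "anomalous" for r in test])
        assert np.median(scores[labels]) > np.median(scores[~labels])
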