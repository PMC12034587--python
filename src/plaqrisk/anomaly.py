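"""Reconstruction-based patch anomaly models and their scores.

Two model families, both trained on patches from event-free patients only:

* a convolutional autoencoder (primary): three conv+ReLU+max-pool encoder
  stages ending in a 128-channel feature map, flattened to a 512-dimensional
  latent code (defaults; both configurable), mirrored by three transposed-conv
  decoder stages, the first two with ReLU and the last with a sigmoid. Its
  anomaly score is the mean squared error between a patch and its
  reconstruction, averaged over every pixel-channel entry:

      A(x) = |x - D(E(x))|^2 / n

* an f-AnoGAN of the izif form (optional): a Wasserstein GAN is trained
  first, the checkpoint with the lowest Fréchet distance on the training set
  is kept, then an encoder is trained into the frozen generator's latent
  space with early stopping. Its score adds an image residual and a
  discriminator-feature residual:

      A(x) = |x - G(E(x))|^2 / n + |f(x) - f(G(E(x)))|^2 / n_d

Inputs are RGB patches scaled to [0, 1] (the decoder/generator sigmoid fixes
the output range), so the autoencoder score of an in-range input is at most 1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import nn
from .patching import PatchRecord

__all__ = [
    "AutoencoderSpec", "TrainConfig", "ConvAutoencoder",
    "save_autoencoder", "load_autoencoder",
    "reconstruction_score", "izif_score", "autoencoder_score", "fanogan_score",
    "score_patches", "train_autoencoder",
    "FanoganSpec", "FanoganModel", "train_fanogan",
    "select_checkpoint", "EarlyStopper", "embed_images", "frechet_distance",
]


# ---------------------------------------------------------------------------
# score formulas (pure)
# ---------------------------------------------------------------------------

def reconstruction_score(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Autoencoder anomaly score: MSE over all n scalar entries of x."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    diff = x - x_hat
    return float(np.sum(diff * diff) / x.size)


def izif_score(x: np.ndarray, x_hat: np.ndarray,
               f_x: np.ndarray, f_x_hat: np.ndarray) -> float:
    """izif anomaly score: image residual / n plus feature residual / n_d."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    f_x = np.asarray(f_x, dtype=np.float64)
    f_x_hat = np.asarray(f_x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"image shape mismatch: {x.shape} vs {x_hat.shape}")
    if f_x.shape != f_x_hat.shape:
        raise ValueError(f"feature shape mismatch: {f_x.shape} vs {f_x_hat.shape}")
    d_img = x - x_hat
    d_feat = f_x - f_x_hat
    return float(np.sum(d_img * d_img) / x.size + np.sum(d_feat * d_feat) / f_x.size)


# ---------------------------------------------------------------------------
# convolutional autoencoder
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AutoencoderSpec:
    """Architecture sizes. The default profile (256 px, 32->64->128 channels,
    512-dim latent) matches full-resolution patches; the small desk profile
    (64 px, 8->16->32, 128-dim) trains in minutes on one CPU."""

    input_px: int = 256
    channels: tuple[int, int, int] = (32, 64, 128)
    latent_dim: int = 512

    def validate(self) -> None:
        if self.input_px % 8 != 0 or self.input_px < 8:
            raise ValueError("input_px must be a positive multiple of 8")
        if len(self.channels) != 3 or min(self.channels) < 1:
            raise ValueError("need three positive channel widths")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    early_stop_patience: int = 30
    seed: int = 0

    def validate(self) -> None:
        if min(self.epochs, self.batch_size, self.early_stop_patience) < 1:
            raise ValueError("epochs, batch_size, patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError("optimizer must be 'adam' or 'rmsprop'")


class ConvAutoencoder:
    def __init__(self, spec: AutoencoderSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        c1, c2, c3 = spec.channels
        s = spec.input_px // 8  # after three 2x2 pools
        feat = c3 * s * s
        self.encoder = nn.Sequential(
            nn.Conv2d(3, c1, rng=rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(c1, c2, rng=rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(c2, c3, rng=rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Flatten(), nn.Dense(feat, spec.latent_dim, rng=rng),
        )
        self.decoder = nn.Sequential(
            nn.Dense(spec.latent_dim, feat, rng=rng), nn.ReLU(),
            nn.Reshape((c3, s, s)),
            nn.ConvTranspose2x2(c3, c2, rng=rng), nn.ReLU(),
            nn.ConvTranspose2x2(c2, c1, rng=rng), nn.ReLU(),
            nn.ConvTranspose2x2(c1, 3, rng=rng), nn.Sigmoid(),
        )
        self.net = nn.Sequential(self.encoder, self.decoder)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) in [0, 1] -> reconstruction of the same shape."""
        return self.net.forward(x.astype(np.float32))


def _records_to_batch(patches: Sequence[PatchRecord]) -> np.ndarray:
    arrs = []
    for r in patches:
        if r.pixels is None:
            raise ValueError(f"patch at ({r.x0}, {r.y0}) has no pixel data")
        arrs.append(r.pixels_float().transpose(2, 0, 1))
    return np.stack(arrs)


def autoencoder_score(model: ConvAutoencoder, patch: PatchRecord) -> float:
    """Eq.-style MSE anomaly score A(x) for one patch."""
    x = _records_to_batch([patch])
    x_hat = model.reconstruct(x)
    return reconstruction_score(x[0], x_hat[0])


def score_patches(model, patches: Sequence[PatchRecord],
                  batch_size: int = 64) -> np.ndarray:
    """Vectorized per-patch anomaly scores (autoencoder or f-AnoGAN model)."""
    scores = np.empty(len(patches), dtype=np.float64)
    if isinstance(model, FanoganModel):
        for i, r in enumerate(patches):
            scores[i] = fanogan_score(model, r)
        return scores
    for start in range(0, len(patches), batch_size):
        chunk = patches[start:start + batch_size]
        x = _records_to_batch(chunk)
        x_hat = model.reconstruct(x)
        d = (x.astype(np.float64) - x_hat.astype(np.float64)) ** 2
        scores[start:start + len(chunk)] = d.reshape(len(chunk), -1).mean(axis=1)
    return scores


class EarlyStopper:
    """Stop when the monitored loss has not strictly improved for `patience`
    consecutive epochs."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, loss: float) -> bool:
        """Record one epoch loss; return True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _guard_normal_only(patches: Sequence[PatchRecord]) -> None:
    bad = [r for r in patches if r.label == "anomalous"]
    if bad:
        raise ValueError(
            f"{len(bad)} anomalous-labelled patches in a normal-only training set")


def train_autoencoder(patches: Sequence[PatchRecord], spec: AutoencoderSpec,
                      cfg: TrainConfig) -> tuple[ConvAutoencoder, list[float]]:
    """Train the autoencoder on normal patches; returns (model, loss curve).

    Minimizes reconstruction MSE with the configured optimizer; fully
    deterministic for a fixed ``cfg.seed``. Raises if any training patch is
    labelled anomalous (leakage guard) or no full batch can be formed.
    """
    cfg.validate()
    _guard_normal_only(patches)
    if len(patches) < 1:
        raise ValueError("no training patches")
    x_all = _records_to_batch(patches)
    rng = np.random.default_rng(cfg.seed)
    model = ConvAutoencoder(spec, rng)
    opt_cls = nn.Adam if cfg.optimizer == "adam" else nn.RMSprop
    opt = opt_cls(model.net.params(), lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.early_stop_patience)
    losses: list[float] = []
    n = x_all.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            xb = x_all[order[start:start + cfg.batch_size]]
            y = model.net.forward(xb)
            loss, grad = nn.mse_loss(y, xb)
            model.net.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
        if stopper.update(losses[-1]):
            break
    return model, losses


def save_autoencoder(model: ConvAutoencoder, path, cfg: TrainConfig | None = None) -> None:
    """Checkpoint to <path>.npz with a JSON sidecar holding spec and config."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.net.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"spec": dataclasses.asdict(model.spec)}
    if cfg is not None:
        sidecar["train_config"] = dataclasses.asdict(cfg)
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_autoencoder(path) -> ConvAutoencoder:
    """Rebuild a checkpointed autoencoder from <path>.npz + sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_d = sidecar["spec"]
    spec = AutoencoderSpec(input_px=spec_d["input_px"],
                           channels=tuple(spec_d["channels"]),
                           latent_dim=spec_d["latent_dim"])
    model = ConvAutoencoder(spec, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        for i, (p, _) in enumerate(model.net.params()):
            p[...] = data[f"p{i}"]
    return model


# ---------------------------------------------------------------------------
# f-AnoGAN (izif variant)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FanoganSpec:
    """Sizes for the izif f-AnoGAN. Defaults follow the full profile
    (1024-dim latent); the desk profile uses 32 px inputs and a small latent."""

    input_px: int = 64
    latent_dim: int = 1024
    gen_channels: tuple[int, int] = (64, 32)
    critic_channels: tuple[int, int] = (32, 64)

    def validate(self) -> None:
        if self.input_px % 4 != 0 or self.input_px < 8:
            raise ValueError("input_px must be a positive multiple of 4")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclasses.dataclass
class FanoganTrainConfig:
    gan_epochs: int = 300
    encoder_epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 5e-5
    n_critic: int = 5
    clip_value: float = 0.05
    checkpoint_every: int = 5
    encoder_patience: int = 30
    feature_weight: float = 1.0  # izif weighting of the feature residual
    seed: int = 0


class FanoganModel:
    """Generator, critic, and izif encoder; built untrained."""

    def __init__(self, spec: FanoganSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        g1, g2 = spec.gen_channels
        d1, d2 = spec.critic_channels
        s = spec.input_px // 4
        self.generator = nn.Sequential(
            nn.Dense(spec.latent_dim, g1 * s * s, rng=rng), nn.ReLU(),
            nn.Reshape((g1, s, s)),
            nn.ConvTranspose2x2(g1, g2, rng=rng), nn.ReLU(),
            nn.ConvTranspose2x2(g2, 3, rng=rng), nn.Sigmoid(),
        )
        # critic features f(.): the layer before the final (linear) layer
        self.critic_features = nn.Sequential(
            nn.Conv2d(3, d1, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(d1, d2, stride=2, rng=rng), nn.ReLU(),
            nn.Flatten(),
        )
        self.feature_dim = d2 * s * s
        self.critic_head = nn.Dense(self.feature_dim, 1, rng=rng)
        self.encoder = nn.Sequential(
            nn.Conv2d(3, d1, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(d1, d2, stride=2, rng=rng), nn.ReLU(),
            nn.Flatten(), nn.Dense(self.feature_dim, spec.latent_dim, rng=rng),
        )
        self.gan_trained = False
        self.encoder_trained = False

    def critic(self, x: np.ndarray) -> np.ndarray:
        return self.critic_head.forward(self.critic_features.forward(x))

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.generator.forward(self.encoder.forward(x.astype(np.float32)))


def fanogan_score(model: FanoganModel, patch: PatchRecord) -> float:
    """izif anomaly score for one patch using the trained G, f, E."""
    if not (model.gan_trained and model.encoder_trained):
        raise ValueError("f-AnoGAN model has untrained components")
    x = _records_to_batch([patch])
    x_hat = model.generator.forward(model.encoder.forward(x))
    f_x = model.critic_features.forward(x)
    f_hat = model.critic_features.forward(x_hat)
    return izif_score(x[0], x_hat[0], f_x[0], f_hat[0])


def embed_images(images: np.ndarray, dim: int = 16, seed: int = 12345) -> np.ndarray:
    """Lightweight image embedding for Fréchet-distance checkpointing.

    Block-averages each image to 8x8 per channel and applies a fixed seeded
    Gaussian projection to ``dim`` components. Serves as the feature extractor
    behind the checkpoint-selection interface; the selection logic itself is
    the tested part.
    """
    n, c, h, w = images.shape
    f = max(h // 8, 1)
    h2, w2 = (h // f) * f, (w // f) * f
    pooled = images[:, :, :h2, :w2].reshape(n, c, h2 // f, f, w2 // f, f).mean(axis=(3, 5))
    flat = pooled.reshape(n, -1).astype(np.float64)
    proj = np.random.default_rng(seed).normal(size=(flat.shape[1], dim)) / np.sqrt(flat.shape[1])
    return flat @ proj


def frechet_distance(feats_a: np.ndarray, feats_b: np.ndarray, eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussians fitted to two feature sets."""
    from scipy import linalg

    mu_a, mu_b = feats_a.mean(axis=0), feats_b.mean(axis=0)
    cov_a = np.cov(feats_a, rowvar=False) + eps * np.eye(feats_a.shape[1])
    cov_b = np.cov(feats_b, rowvar=False) + eps * np.eye(feats_b.shape[1])
    covmean = linalg.sqrtm(cov_a @ cov_b)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    diff = mu_a - mu_b
    return float(diff @ diff + np.trace(cov_a + cov_b - 2.0 * covmean))


def select_checkpoint(fid_scores: Sequence[float]) -> int:
    """Index of the checkpoint with the lowest FID (first on ties)."""
    if len(fid_scores) == 0:
        raise ValueError("no checkpoints")
    return int(np.argmin(fid_scores))


def _snapshot(seq: nn.Sequential) -> list[np.ndarray]:
    return [p.copy() for p, _ in seq.params()]


def _restore(seq: nn.Sequential, snap: list[np.ndarray]) -> None:
    for (p, _), saved in zip(seq.params(), snap):
        p[...] = saved


def train_fanogan(patches: Sequence[PatchRecord], spec: FanoganSpec,
                  cfg: FanoganTrainConfig) -> tuple[FanoganModel, dict]:
    """Two-phase izif training on normal patches.

    Phase 1 trains the Wasserstein GAN (weight-clipped critic, RMSprop at the
    configured rate), snapshotting the generator every ``checkpoint_every``
    epochs and keeping the snapshot with the lowest Fréchet distance between
    training-set and generated embeddings. Phase 2 trains the encoder against
    the frozen generator and critic features, stopping after
    ``encoder_patience`` epochs without improvement of the izif loss.
    """
    _guard_normal_only(patches)
    x_all = _records_to_batch(patches)
    rng = np.random.default_rng(cfg.seed)
    model = FanoganModel(spec, rng)
    log = _train_gan(model, x_all, cfg, rng)
    log["encoder_losses"] = _train_encoder(model, x_all, cfg, rng)
    return model, log


def _train_gan(model: FanoganModel, x_all: np.ndarray,
               cfg: FanoganTrainConfig, rng: np.random.Generator) -> dict:
    n = x_all.shape[0]
    opt_g = nn.RMSprop(model.generator.params(), lr=cfg.learning_rate)
    critic_params = model.critic_features.params() + model.critic_head.params()
    opt_d = nn.RMSprop(critic_params, lr=cfg.learning_rate)
    real_emb = embed_images(x_all)
    fids: list[float] = []
    snaps: list[list[np.ndarray]] = []
    for epoch in range(cfg.gan_epochs):
        order = rng.permutation(n)
        step = 0
        for start in range(0, n, cfg.batch_size):
            xb = x_all[order[start:start + cfg.batch_size]]
            z = rng.normal(size=(xb.shape[0], model.spec.latent_dim)).astype(np.float32)
            fake = model.generator.forward(z)
            # critic update: one step on the Wasserstein loss
            # mean D(fake) - mean D(real), real and fake stacked in one batch
            m = xb.shape[0]
            d_both = model.critic(np.concatenate([xb, fake], axis=0))
            g = np.concatenate([np.full((m, 1), -1.0 / m, dtype=np.float32),
                                np.full((m, 1), 1.0 / m, dtype=np.float32)])
            model.critic_features.backward(model.critic_head.backward(g))
            opt_d.step()
            del d_both
            for p, _ in critic_params:
                np.clip(p, -cfg.clip_value, cfg.clip_value, out=p)
            # generator update every n_critic steps: maximize D(fake)
            step += 1
            if step % cfg.n_critic == 0:
                fake = model.generator.forward(z)
                d_fake = model.critic(fake)
                g = np.full_like(d_fake, -1.0 / d_fake.size)
                gx = model.critic_features.backward(model.critic_head.backward(g))
                model.generator.backward(gx)
                opt_g.step()
        if (epoch + 1) % cfg.checkpoint_every == 0 or epoch == cfg.gan_epochs - 1:
            z = np.random.default_rng(cfg.seed + 999).normal(
                size=(min(n, 128), model.spec.latent_dim)).astype(np.float32)
            fake_emb = embed_images(model.generator.forward(z))
            fids.append(frechet_distance(real_emb, fake_emb))
            snaps.append(_snapshot(model.generator))
    best = select_checkpoint(fids)
    _restore(model.generator, snaps[best])
    model.gan_trained = True
    return {"fid_scores": fids, "selected_checkpoint": best}


def _train_encoder(model: FanoganModel, x_all: np.ndarray,
                   cfg: FanoganTrainConfig, rng: np.random.Generator) -> list[float]:
    if not model.gan_trained:
        raise RuntimeError("encoder training requires a trained GAN")
    n = x_all.shape[0]
    opt_e = nn.Adam(model.encoder.params(), lr=1e-3)
    stopper = EarlyStopper(cfg.encoder_patience)
    losses: list[float] = []
    kappa = cfg.feature_weight
    for _epoch in range(cfg.encoder_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            xb = x_all[order[start:start + cfg.batch_size]]
            f_x = model.critic_features.forward(xb).copy()
            z = model.encoder.forward(xb)
            xg = model.generator.forward(z)
            f_g = model.critic_features.forward(xg)
            loss_img, g_img = nn.mse_loss(xg, xb)
            loss_feat, g_feat = nn.mse_loss(f_g, f_x)
            g_xg = g_img + kappa * model.critic_features.backward(g_feat)
            gz = model.generator.backward(g_xg)
            model.encoder.backward(gz)
            opt_e.step()
            epoch_losses.append(loss_img + kappa * loss_feat)
        losses.append(float(np.mean(epoch_losses)))
        if stopper.update(losses[-1]):
            break
    model.encoder_trained = True
    return losses
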