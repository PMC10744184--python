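"""Residual-learning GAN denoiser: patching, training, and full-image inference.

The generator is an encoder-decoder CNN that maps a noisy patch to a predicted
*noise* patch; the clean estimate is input minus prediction.  Training pairs
are built by adding synthetic Poisson-Gaussian noise at a grid of (alpha, beta)
levels to clean images: the input is the noisy image and the label is
input - clean, i.e. the exact noise map.  The generator minimizes MSE to the
label plus a small adversarial term from a convolutional discriminator that
scores noise patches as real (sampled) or fake (generated).

Full images are denoised by optional bilinear resize, tiling into patches from
origin (0, 0) at a stride equal to the patch size, per-patch noise prediction,
stitching, cropping the reflect-padded margins, resizing back, and subtracting
the stitched noise map from the input.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .exceptions import SizeError
from .images import Image2D
from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dense,
                 GlobalAvgPool, LeakyReLU, ReLU, Sequential, bce_with_logits,
                 mse_loss, sigmoid)
from .noise import NoiseParams, add_noise


@dataclass
class GANConfig:
    """Architecture and training hyperparameters.

    The reference-scale defaults (256 px patches, channels 128-1024, 200
    epochs, batch 16, Adam at 5e-4, MSE objective) describe the full-size
    configuration; :func:`desk_config` returns the small configuration used
    for CPU-scale experiments and tests.
    """

    patch_size: int = 256
    stride: int = 256
    epochs: int = 200
    batch_size: int = 16
    channels: tuple[int, ...] = (128, 256, 512, 1024)
    learning_rate: float = 5e-4
    adv_weight: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.1
    resize_to: tuple[int, int] | None = None
    # band limit for the predicted noise map: wavelengths longer than ~half a
    # patch cannot be attributed by patch-local inference, so the prediction
    # is high-pass filtered at this Gaussian sigma (px) before subtraction.
    # None = patch_size / 16; 0 disables the filter.
    highpass_sigma: float | None = None

    @property
    def effective_highpass_sigma(self) -> float:
        if self.highpass_sigma is None:
            return self.patch_size / 16.0
        return float(self.highpass_sigma)

    def __post_init__(self):
        self.channels = tuple(int(c) for c in self.channels)
        if self.patch_size % (2 ** len(self.channels)) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by "
                f"2^{len(self.channels)} for the encoder-decoder geometry"
            )
        if self.stride > self.patch_size or self.stride < 1:
            raise ValueError("stride must lie in [1, patch_size]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        if self.resize_to is not None:
            d["resize_to"] = list(self.resize_to)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GANConfig":
        d = dict(d)
        if d.get("resize_to") is not None:
            d["resize_to"] = tuple(d["resize_to"])
        d["channels"] = tuple(d.get("channels", (128, 256, 512, 1024)))
        return cls(**d)


def desk_config(**overrides) -> GANConfig:
    """Small CPU-scale configuration: 64 px patches, channels (16, 32), 20 epochs."""
    base = dict(patch_size=64, stride=64, epochs=20, batch_size=16,
                channels=(16, 32), learning_rate=1e-3, adv_weight=1e-3, seed=0)
    base.update(overrides)
    return GANConfig(**base)


@dataclass
class PatchSet:
    """Patches with their origins plus the geometry needed to invert tiling."""

    patches: list[tuple[np.ndarray, int, int]]
    source_shape: tuple[int, int]
    resized_shape: tuple[int, int]   # reflect-padded shape actually tiled
    patch_size: int
    stride: int
    pixel_size: float = 1.0


@dataclass
class TrainedDenoiser:
    generator: Sequential
    discriminator: Sequential
    config: GANConfig
    training_log: list[dict] = field(default_factory=list)
    divisor: float = 1.0             # normalization used during training


# ---------------------------------------------------------------------------
# geometry


def resize_bilinear(image: Image2D, target_height: int, target_width: int
                    ) -> Image2D:
    """Bilinear resize with corner-aligned sampling (endpoints map to endpoints).

    The pixel pitch is rescaled by the row factor so physical extent is
    approximately preserved.
    """
    if target_height < 1 or target_width < 1:
        raise ValueError("target dimensions must be >= 1")
    h, w = image.shape
    if (target_height, target_width) == (h, w):
        return image.copy()
    rows = np.linspace(0, h - 1, target_height) if target_height > 1 else np.array([0.0])
    cols = np.linspace(0, w - 1, target_width) if target_width > 1 else np.array([0.0])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(image.pixels, [rr, cc], order=1, mode="nearest")
    scale = h / target_height
    return Image2D(out, image.pixel_size * scale)


def _padded_extent(n: int, patch: int, stride: int) -> int:
    if n <= patch:
        return patch
    return patch + math.ceil((n - patch) / stride) * stride


def extract_patches(image: Image2D, config: GANConfig) -> PatchSet:
    """Row-major tiling from origin (0, 0); the image is reflect-padded on the
    bottom/right so the patch grid covers it exactly."""
    p, s = config.patch_size, config.stride
    h, w = image.shape
    hp, wp = _padded_extent(h, p, s), _padded_extent(w, p, s)
    arr = image.pixels
    if (hp, wp) != (h, w):
        arr = np.pad(arr, ((0, hp - h), (0, wp - w)), mode="reflect")
    patches = [(arr[r:r + p, c:c + p].copy(), r, c)
               for r in range(0, hp - p + 1, s)
               for c in range(0, wp - p + 1, s)]
    return PatchSet(patches=patches, source_shape=(h, w), resized_shape=(hp, wp),
                    patch_size=p, stride=s, pixel_size=image.pixel_size)


def stitch_patches(patchset: PatchSet) -> Image2D:
    """Inverse of :func:`extract_patches` for stride = patch size: place each
    patch at its origin and crop the padding back off."""
    if patchset.stride != patchset.patch_size:
        raise ValueError("stitching requires non-overlapping patches "
                         "(stride == patch_size)")
    hp, wp = patchset.resized_shape
    canvas = np.full((hp, wp), np.nan)
    for patch, r, c in patchset.patches:
        canvas[r:r + patchset.patch_size, c:c + patchset.patch_size] = patch
    if np.isnan(canvas).any():
        raise SizeError("patch set does not cover the frame (missing tile)")
    h, w = patchset.source_shape
    return Image2D(canvas[:h, :w], patchset.pixel_size)


# ---------------------------------------------------------------------------
# training data


def make_training_pairs(clean_images: list[Image2D],
                        params_grid: list[NoiseParams],
                        config: GANConfig, seed: int = 0
                        ) -> list[tuple[np.ndarray, np.ndarray]]:
    """(noisy patch, noise-label patch) pairs over images x noise levels.

    label = noisy - clean pixel-exactly, so input - label recovers the clean
    patch; patches are extracted in lockstep from the noisy image and the
    noise map.
    """
    if not clean_images:
        raise ValueError("need at least one clean image")
    if not params_grid:
        raise ValueError("noise parameter grid must be non-empty")
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for i, clean in enumerate(clean_images):
        for j, params in enumerate(params_grid):
            sub = int(np.random.SeedSequence([seed & 0x7FFFFFFF, i, j])
                      .generate_state(1)[0] % 2 ** 31)
            noisy = add_noise(clean, params, sub)
            label = Image2D(noisy.pixels - clean.pixels, clean.pixel_size)
            ps_in = extract_patches(noisy, config)
            ps_lab = extract_patches(label, config)
            for (xin, _, _), (lab, _, _) in zip(ps_in.patches, ps_lab.patches):
                pairs.append((xin, lab))
    return pairs


# ---------------------------------------------------------------------------
# models


def build_generator(config: GANConfig, rng: np.random.Generator) -> Sequential:
    """Encoder (stride-2 convs) + mirrored decoder, no skip connections.

    Batch norm + ReLU after every layer except the final transposed
    convolution, which is linear so the predicted noise can take both signs.
    The output layer starts at zero weights so training begins at the identity
    denoiser (predicted noise = 0) and can only improve on it.
    """
    layers: list = []
    c_in = 1
    for c in config.channels:
        layers += [Conv2d(c_in, c, k=3, stride=2, pad=1, rng=rng),
                   BatchNorm2d(c), ReLU()]
        c_in = c
    for c in reversed(config.channels[:-1]):
        layers += [ConvTranspose2d(c_in, c, k=4, stride=2, pad=1, rng=rng),
                   BatchNorm2d(c), ReLU()]
        c_in = c
    final = ConvTranspose2d(c_in, 1, k=4, stride=2, pad=1, rng=rng)
    final.params["W"][...] = 0.0
    layers += [final]
    return Sequential(layers)


def build_discriminator(config: GANConfig, rng: np.random.Generator) -> Sequential:
    """Strided convolutional classifier ending in a logit (sigmoid applied by
    the caller); channels scale with the generator's."""
    layers: list = []
    c_in = 1
    for c in config.channels:
        layers += [Conv2d(c_in, max(4, c // 4), k=3, stride=2, pad=1, rng=rng),
                   LeakyReLU(0.2)]
        c_in = max(4, c // 4)
    layers += [GlobalAvgPool(), Dense(c_in, 1, rng=rng)]
    return Sequential(layers)


def discriminator_score(disc: Sequential, patches: np.ndarray) -> np.ndarray:
    """Probability in (0, 1) that each patch is a real sampled noise map."""
    return sigmoid(disc.forward(patches, train=False))[:, 0]


# ---------------------------------------------------------------------------
# training


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n - batch_size + 1, batch_size):
        yield idx[start:start + batch_size]


def train_gan(pairs: list[tuple[np.ndarray, np.ndarray]],
              config: GANConfig) -> TrainedDenoiser:
    """Alternating adversarial training of the residual generator.

    Discriminator: BCE on real (sampled noise) vs fake (generated) patches.
    Generator: MSE to the noise label + adv_weight x non-saturating
    adversarial loss.  A 90/10 train/validation split (seeded shuffle) tracks
    held-out generator MSE; the parameters of the best epoch are returned.
    """
    if not pairs:
        raise ValueError("no training pairs supplied")
    x = np.stack([p[0] for p in pairs])[:, None].astype(np.float64)
    y = np.stack([p[1] for p in pairs])[:, None].astype(np.float64)
    n = x.shape[0]
    if config.batch_size > n:
        raise ValueError(f"batch size {config.batch_size} exceeds dataset size {n}")
    divisor = float(max(np.abs(x).max(), 1e-8))
    x /= divisor
    y /= divisor

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) < config.batch_size:
        raise ValueError("not enough training pairs after the validation split")
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    gen = build_generator(config, rng)
    disc = build_discriminator(config, rng)
    opt_g = Adam(gen, lr=config.learning_rate)
    opt_d = Adam(disc, lr=config.learning_rate)

    log: list[dict] = []
    best_val = np.inf
    best_state: dict | None = None
    for epoch in range(config.epochs):
        g_losses, d_losses = [], []
        for batch in _as_batches(len(xt), config.batch_size, rng):
            xb, yb = xt[batch], yt[batch]
            fake = gen.forward(xb, train=True)

            if config.adv_weight > 0:
                disc.zero_grads()
                logit_real = disc.forward(yb, train=True)
                loss_real, g_real = bce_with_logits(logit_real,
                                                    np.ones_like(logit_real))
                disc.backward(g_real)
                logit_fake = disc.forward(fake, train=True)
                loss_fake, g_fake = bce_with_logits(logit_fake,
                                                    np.zeros_like(logit_fake))
                disc.backward(g_fake)
                opt_d.step()
                d_losses.append(loss_real + loss_fake)

            gen.zero_grads()
            loss_mse, g_out = mse_loss(fake, yb)
            if config.adv_weight > 0:
                disc.zero_grads()
                logit_fake = disc.forward(fake, train=True)
                loss_adv, g_adv_logit = bce_with_logits(
                    logit_fake, np.ones_like(logit_fake))
                g_out = g_out + config.adv_weight * disc.backward(g_adv_logit)
                disc.zero_grads()   # discard grads from the generator pass
            gen.backward(g_out)
            opt_g.step()
            if not np.isfinite(loss_mse):
                raise RuntimeError(
                    f"NaN/inf generator loss at epoch {epoch}; lower the "
                    f"learning rate or check input scaling"
                )
            g_losses.append(loss_mse)

        val_pred = gen.forward(xv, train=False)
        val_mse = float(np.mean((val_pred - yv) ** 2))
        log.append({"epoch": epoch,
                    "gen_mse": float(np.mean(g_losses)),
                    "disc_loss": float(np.mean(d_losses)) if d_losses else 0.0,
                    "val_mse": val_mse})
        if val_mse < best_val:
            best_val = val_mse
            best_state = copy.deepcopy(gen.state_arrays())
    if best_state is not None:
        gen.load_state_arrays(best_state)
    return TrainedDenoiser(generator=gen, discriminator=disc, config=config,
                           training_log=log, divisor=divisor)


# ---------------------------------------------------------------------------
# inference


def predict_noise(model: TrainedDenoiser, image: Image2D,
                  batch_size: int = 16) -> Image2D:
    """Stitched generator prediction of the noise map for a full image."""
    config = model.config
    infer_cfg = copy.copy(config)
    infer_cfg.stride = config.patch_size     # non-overlapping for exact stitching
    if config.resize_to is not None:
        work = resize_bilinear(image, *config.resize_to)
    else:
        work = image
    ps = extract_patches(work, infer_cfg)
    x = np.stack([p for p, _, _ in ps.patches])[:, None] / model.divisor
    preds = []
    for start in range(0, x.shape[0], batch_size):
        preds.append(model.generator.forward(x[start:start + batch_size],
                                             train=False))
    pred = np.concatenate(preds)[:, 0] * model.divisor
    out_ps = PatchSet(
        patches=[(pred[i], r, c) for i, (_, r, c) in enumerate(ps.patches)],
        source_shape=ps.source_shape, resized_shape=ps.resized_shape,
        patch_size=ps.patch_size, stride=ps.stride, pixel_size=ps.pixel_size)
    noise_map = stitch_patches(out_ps)
    sigma = config.effective_highpass_sigma
    if sigma > 0:
        filtered = noise_map.pixels - ndimage.gaussian_filter(noise_map.pixels,
                                                              sigma)
        noise_map = Image2D(filtered, noise_map.pixel_size)
    if config.resize_to is not None:
        noise_map = resize_bilinear(noise_map, *image.shape)
    if noise_map.shape != image.shape:
        raise RuntimeError("internal error: stitched map shape mismatch")
    return Image2D(noise_map.pixels, image.pixel_size)


def denoise(model: TrainedDenoiser, noisy: Image2D) -> Image2D:
    """Clean estimate: input minus the predicted noise map."""
    noise_map = predict_noise(model, noisy)
    return Image2D(noisy.pixels - noise_map.pixels, noisy.pixel_size)


# ---------------------------------------------------------------------------
# persistence


def save_denoiser(model: TrainedDenoiser, path) -> None:
    """Checkpoint: .npz with all arrays + YAML sidecar (config, divisor)."""
    path = Path(path)
    arrays = {f"gen.{k}": v for k, v in model.generator.state_arrays().items()}
    arrays.update({f"disc.{k}": v
                   for k, v in model.discriminator.state_arrays().items()})
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump({
        "config": model.config.to_dict(),
        "divisor": model.divisor,
        "training_log": model.training_log,
    }, sort_keys=False))


def load_denoiser(path) -> TrainedDenoiser:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    config = GANConfig.from_dict(meta["config"])
    rng = np.random.default_rng(config.seed)
    gen = build_generator(config, rng)
    disc = build_discriminator(config, rng)
    with np.load(path) as data:
        gen.load_state_arrays({k[len("gen."):]: data[k]
                               for k in data.files if k.startswith("gen.")})
        disc.load_state_arrays({k[len("disc."):]: data[k]
                                for k in data.files if k.startswith("disc.")})
    return TrainedDenoiser(generator=gen, discriminator=disc, config=config,
                           training_log=meta.get("training_log", []),
                           divisor=float(meta["divisor"]))
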