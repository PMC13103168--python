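"""Compact convolutional GAN for grayscale images.

The generator maps a latent vector z (standard-normal, dimension
``latent_dim``) through stacked transposed-convolution + batchnorm + ReLU
blocks, doubling spatial size from 4x4 up to the target resolution, and
squashes to (-1, 1) with a final Tanh.  The discriminator mirrors it with
strided convolutions, batchnorm and LeakyReLU, ending in a sigmoid
probability of "real".  Both networks train adversarially with binary
cross-entropy and Adam (lr 0.001, betas (0.5, 0.999)) for a fixed number
of alternating update steps (999 by default); the generator uses the
non-saturating objective (trained against the "real" target).

Weights are initialized with the standard scheme for this architecture
family: convolution weights ~ N(0, 0.02); batchnorm scales ~ N(1, 0.02),
shifts 0.

After training the generator is used as a *fixed* deterministic decoder
(batchnorm in evaluation mode, frozen running statistics) for latent-space
inversion; :func:`generator_forward` / :func:`generator_backward_to_z`
expose the differentiable path the inversion optimizer needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import ConfigurationError, TrainingDivergenceError, ValidationError
from .synthetic import ImageSample, ViewLabel

_SUPPORTED_RESOLUTIONS = (16, 32, 64, 128)


@dataclass
class GanConfig:
    latent_dim: int = 100
    resolution: int = 64
    base_feature_maps: int = 64
    learning_rate: float = 0.001
    beta1: float = 0.5
    beta2: float = 0.999
    train_steps: int = 999
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> "GanConfig":
        if self.latent_dim < 1:
            raise ValidationError(f"latent_dim: must be positive, got {self.latent_dim}")
        if self.resolution not in _SUPPORTED_RESOLUTIONS:
            raise ConfigurationError(
                f"resolution: must be one of {_SUPPORTED_RESOLUTIONS} "
                f"(power-of-two multiple of 4), got {self.resolution}")
        for name in ("base_feature_maps", "train_steps", "batch_size"):
            if getattr(self, name) < 1 and not (name == "train_steps" and self.train_steps == 0):
                raise ValidationError(f"{name}: must be positive")
        if self.learning_rate <= 0:
            raise ValidationError(f"learning_rate: must be positive, got {self.learning_rate}")
        for name in ("beta1", "beta2"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValidationError(f"{name}: must be in (0, 1)")
        return self


@dataclass
class GanModels:
    """Paired generator/discriminator with their configuration."""

    generator: nn.Sequential
    discriminator: nn.Sequential
    config: GanConfig

    @property
    def generator_params(self) -> dict[str, np.ndarray]:
        return self.generator.state_arrays()

    @property
    def discriminator_params(self) -> dict[str, np.ndarray]:
        return self.discriminator.state_arrays()


@dataclass
class TrainTrace:
    generator_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)
    monitor_latents: np.ndarray | None = None
    monitor_images_every: int = 100


def _n_blocks(resolution: int) -> int:
    return int(np.log2(resolution // 4))


def _build_generator(cfg: GanConfig) -> nn.Sequential:
    nb = _n_blocks(cfg.resolution)
    ch = cfg.base_feature_maps * 2 ** (nb - 1)
    layers: list[nn.Layer] = [
        nn.ConvTranspose2d(cfg.latent_dim, ch, 4, 1, 0),
        nn.BatchNorm2d(ch), nn.ReLU(),
    ]
    for _ in range(nb - 1):
        layers += [nn.ConvTranspose2d(ch, ch // 2, 4, 2, 1),
                   nn.BatchNorm2d(ch // 2), nn.ReLU()]
        ch //= 2
    layers += [nn.ConvTranspose2d(ch, 1, 4, 2, 1), nn.Tanh()]
    return nn.Sequential(layers)


def _build_discriminator(cfg: GanConfig) -> nn.Sequential:
    nb = _n_blocks(cfg.resolution)
    ch = cfg.base_feature_maps
    # first block has no batchnorm (its input is the raw image)
    layers: list[nn.Layer] = [nn.Conv2d(1, ch, 4, 2, 1), nn.LeakyReLU(0.2)]
    for _ in range(nb - 1):
        layers += [nn.Conv2d(ch, ch * 2, 4, 2, 1),
                   nn.BatchNorm2d(ch * 2), nn.LeakyReLU(0.2)]
        ch *= 2
    layers += [nn.Conv2d(ch, 1, 4, 1, 0)]  # logit; sigmoid applied at the surface
    return nn.Sequential(layers)


def init_weights(models: GanModels, seed: int) -> GanModels:
    """Apply the N(0, 0.02) / N(1, 0.02) initialization scheme in place."""
    rng = np.random.default_rng(np.random.SeedSequence(seed % (2 ** 63)))
    for net in (models.generator, models.discriminator):
        for layer in net.layers:
            if isinstance(layer, (nn.Conv2d, nn.ConvTranspose2d)):
                layer.params["w"][...] = rng.normal(
                    0.0, 0.02, layer.params["w"].shape).astype(nn.DTYPE)
            elif isinstance(layer, nn.BatchNorm2d):
                layer.params["gamma"][...] = rng.normal(
                    1.0, 0.02, layer.params["gamma"].shape).astype(nn.DTYPE)
                layer.params["beta"][...] = 0.0
                layer.running_mean[...] = 0.0
                layer.running_var[...] = 1.0
    return models


def build_models(config: GanConfig) -> GanModels:
    """Construct and initialize an untrained generator/discriminator pair."""
    config.validate()
    models = GanModels(_build_generator(config), _build_discriminator(config), config)
    return init_weights(models, config.seed)


# ---------------------------------------------------------------------------
# Forward surfaces
# ---------------------------------------------------------------------------

def generator_forward(models: GanModels, z: np.ndarray, train: bool = False) -> np.ndarray:
    """Decode a (N, latent_dim) batch of latents to (N, 1, H, W) images."""
    z = np.asarray(z, dtype=nn.DTYPE)
    if z.ndim == 1:
        z = z[None, :]
    if z.shape[1] != models.config.latent_dim:
        raise ValidationError(f"z: expected latent length {models.config.latent_dim}, "
                              f"got {z.shape[1]}")
    return models.generator.forward(z[:, :, None, None], train)


def generator_backward_to_z(models: GanModels, d_images: np.ndarray) -> np.ndarray:
    """Backpropagate an image-space gradient to the latents of the last forward."""
    dz = models.generator.backward(d_images)
    return dz.reshape(dz.shape[0], -1)


def generate(models: GanModels, z: np.ndarray) -> ImageSample:
    """Decode one latent vector in evaluation mode (deterministic)."""
    z = np.asarray(z, dtype=nn.DTYPE)
    if z.ndim != 1:
        raise ValidationError(f"z: expected a 1-D latent vector, got ndim {z.ndim}")
    img = generator_forward(models, z, train=False)[0, 0]
    return ImageSample(pixels=np.asarray(img, dtype=np.float64), label=ViewLabel.UNKNOWN)


def discriminate(models: GanModels, images: np.ndarray) -> np.ndarray:
    """Probability-of-real in (0, 1) for a (N, 1, H, W) batch (eval mode)."""
    logits = models.discriminator.forward(np.asarray(images, dtype=nn.DTYPE), False)
    return nn.sigmoid(logits).reshape(-1)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _as_batch_array(images: list[ImageSample]) -> np.ndarray:
    arr = np.stack([s.pixels for s in images]).astype(nn.DTYPE)
    return arr[:, None, :, :]


def train_gan(models: GanModels, images: list[ImageSample],
              config: GanConfig | None = None,
              monitor_batch: int = 16) -> tuple[GanModels, TrainTrace]:
    """Alternating adversarial training for ``config.train_steps`` steps.

    Each step draws a real minibatch and a latent minibatch, updates the
    discriminator on both (targets 1 and 0), then updates the generator on
    a fresh scoring of the same fakes against target 1 (non-saturating
    objective).  Deterministic given config.seed and the input order.
    """
    config = (config or models.config).validate()
    if not images:
        raise ValidationError("images: must be non-empty")
    res = models.config.resolution
    for i, s in enumerate(images):
        if s.pixels.shape != (res, res):
            raise ValidationError(f"images[{i}]: shape {s.pixels.shape} != ({res}, {res})")
    data = _as_batch_array(images)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed % (2 ** 63), spawn_key=(1,)))
    trace = TrainTrace(
        monitor_latents=rng.standard_normal((monitor_batch, config.latent_dim)).astype(nn.DTYPE))

    g_params = [p for _, _, p in models.generator.parameters()]
    d_params = [p for _, _, p in models.discriminator.parameters()]
    opt_g = nn.Adam(g_params, config.learning_rate, config.beta1, config.beta2)
    opt_d = nn.Adam(d_params, config.learning_rate, config.beta1, config.beta2)

    bs = min(config.batch_size, len(images))
    for step in range(config.train_steps):
        idx = rng.choice(len(images), size=bs, replace=len(images) < bs)
        real = data[idx]
        z = rng.standard_normal((bs, config.latent_dim)).astype(nn.DTYPE)

        # --- discriminator update: real -> 1, fake -> 0
        fake = generator_forward(models, z, train=True)
        logits_real = models.discriminator.forward(real, True)
        loss_real, dlog_real = nn.bce_with_logits(logits_real, 1.0)
        models.discriminator.backward(dlog_real)
        grads_real = [layer.grads[name].copy() for layer, name, _ in
                      models.discriminator.parameters()]
        logits_fake = models.discriminator.forward(fake, True)
        loss_fake, dlog_fake = nn.bce_with_logits(logits_fake, 0.0)
        models.discriminator.backward(dlog_fake)
        d_grads = [gr + layer.grads[name] for gr, (layer, name, _) in
                   zip(grads_real, models.discriminator.parameters())]
        d_loss = loss_real + loss_fake
        if not np.isfinite(d_loss):
            raise TrainingDivergenceError(step, "discriminator loss")
        opt_d.step(d_grads)

        # --- generator update: fake -> 1 through the updated discriminator
        fake = generator_forward(models, z, train=True)
        logits = models.discriminator.forward(fake, True)
        g_loss, dlog = nn.bce_with_logits(logits, 1.0)
        if not np.isfinite(g_loss):
            raise TrainingDivergenceError(step, "generator loss")
        d_fake = models.discriminator.backward(dlog)
        models.generator.backward(d_fake)
        opt_g.step([layer.grads[name] for layer, name, _ in models.generator.parameters()])

        trace.discriminator_loss.append(d_loss)
        trace.generator_loss.append(g_loss)
    return models, trace


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(models: GanModels, path, step_count: int | None = None) -> None:
    """Single-archive checkpoint: both parameter sets + config + step count."""
    meta = dict(asdict(models.config))
    meta["step_count"] = step_count if step_count is not None else models.config.train_steps
    arrays = {f"g/{k}": v for k, v in models.generator.state_arrays().items()}
    arrays.update({f"d/{k}": v for k, v in models.discriminator.state_arrays().items()})
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> GanModels:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta.pop("step_count", None)
        config = GanConfig(**meta)
        models = build_models(config)
        models.generator.load_state(
            {k[2:]: data[k] for k in data.files if k.startswith("g/")})
        models.discriminator.load_state(
            {k[2:]: data[k] for k in data.files if k.startswith("d/")})
    return models
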