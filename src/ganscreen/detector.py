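"""Latent-space inversion and the K–S decision rule.

Given a generator trained on in-distribution images, a test image X is
reconstructed by minimizing the reconstruction loss

    L(z) = mean_pixels ( G(z) - X )^2

over the latent z alone (Adam, generator frozen in evaluation mode).  The
mean- rather than sum-of-squares form keeps the loss on the same O(0.1)
scale as the stopping thresholds regardless of resolution.  Optimization
stops when L first drops below the loss threshold tau, after which a fixed
number of extra refinement steps is run; if tau is never reached within
the step budget the sample is declared out-of-distribution outright
(failure to reconstruct is itself OOD evidence).

When the threshold is reached, the pixel-intensity distributions of the
reconstruction and the target are compared with the two-sample
Kolmogorov–Smirnov test on a deterministic spatial subsample (stride
``ks_stride`` per axis; neighbouring pixels are too correlated to count
as independent draws); the sample is in-distribution iff the p-value is
at least the significance level alpha (default 0.05).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import TrainingDivergenceError, ValidationError
from .gan import GanModels, generate, generator_backward_to_z, generator_forward
from .stats import KSTestResult, ks_two_sample
from .synthetic import ImageSample


@dataclass
class InversionConfig:
    learning_rate: float = 0.001
    loss_threshold: float = 0.15
    extra_steps: int = 95
    max_steps: int = 400
    alpha: float = 0.05
    z_seed: int = 0
    restarts: int = 1
    ks_stride: int = 4

    def validate(self) -> "InversionConfig":
        if self.ks_stride < 1:
            raise ValidationError(f"ks_stride: must be >= 1, got {self.ks_stride}")
        if self.loss_threshold <= 0:
            raise ValidationError(f"loss_threshold: must be > 0, got {self.loss_threshold}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError(f"alpha: must be in (0, 1], got {self.alpha}")
        if self.extra_steps < 0:
            raise ValidationError(f"extra_steps: must be >= 0, got {self.extra_steps}")
        if self.max_steps < 1 or self.max_steps < self.extra_steps:
            raise ValidationError(
                f"max_steps: must be >= max(1, extra_steps), got {self.max_steps}")
        if self.learning_rate <= 0:
            raise ValidationError(f"learning_rate: must be > 0, got {self.learning_rate}")
        if self.restarts < 1:
            raise ValidationError(f"restarts: must be >= 1, got {self.restarts}")
        return self


@dataclass
class InversionResult:
    z_final: np.ndarray
    loss_trace: list[float]
    reached_threshold: bool
    steps_to_threshold: int | None
    total_steps: int


class FailureMode(enum.Enum):
    NONE = "none"
    THRESHOLD_NOT_REACHED = "threshold_not_reached"


@dataclass
class DetectionResult:
    is_ood: bool
    ks: KSTestResult | None
    reconstruction_loss: float
    failure_mode: FailureMode
    inversion: InversionResult | None = None


def reconstruction_loss(models: GanModels, z: np.ndarray, x: ImageSample) -> float:
    """Mean squared pixel difference between G(z) and x (0 iff identical)."""
    res = models.config.resolution
    if x.pixels.shape != (res, res):
        raise ValidationError(f"x: shape {x.pixels.shape} != ({res}, {res})")
    img = generator_forward(models, np.asarray(z), train=False)[0, 0]
    diff = img.astype(np.float64) - x.pixels.astype(np.float64)
    return float(np.mean(diff * diff))


def _restart_latent(config: InversionConfig, latent_dim: int, restart: int) -> np.ndarray:
    ss = np.random.SeedSequence(config.z_seed % (2 ** 63), spawn_key=(restart,))
    return np.random.default_rng(ss).standard_normal(latent_dim).astype(nn.DTYPE)


def _invert_once(models: GanModels, x: ImageSample, config: InversionConfig,
                 restart: int) -> InversionResult:
    z = _restart_latent(config, models.config.latent_dim, restart)
    xb = x.pixels.astype(nn.DTYPE)[None, None]
    opt = nn.Adam([z], config.learning_rate, 0.9, 0.999)
    trace: list[float] = []
    s: int | None = None
    for t in range(config.max_steps):
        img = generator_forward(models, z[None, :], train=False)
        diff = img - xb
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise TrainingDivergenceError(t, "inversion loss")
        trace.append(loss)
        if s is None and loss <= config.loss_threshold:
            s = t
        if (s is not None and t >= s + config.extra_steps) or t == config.max_steps - 1:
            break
        dz = generator_backward_to_z(models, (2.0 / diff.size) * diff)[0]
        opt.step([dz])
    return InversionResult(z_final=z.copy(), loss_trace=trace,
                           reached_threshold=s is not None,
                           steps_to_threshold=s, total_steps=len(trace))


def invert(models: GanModels, x: ImageSample, config: InversionConfig) -> InversionResult:
    """Gradient-based latent inversion of one target image.

    With restarts > 1 the restart achieving the lowest final loss wins
    (inversion is non-convex); restart latents are derived deterministically
    from z_seed.
    """
    config.validate()
    x.validate()
    best: InversionResult | None = None
    for r in range(config.restarts):
        result = _invert_once(models, x, config, r)
        if best is None or result.loss_trace[-1] < best.loss_trace[-1]:
            best = result
    return best


def _pixel_ks(recon: np.ndarray, target: np.ndarray, stride: int) -> KSTestResult:
    off = stride // 2
    return ks_two_sample(recon[off::stride, off::stride].ravel(),
                         target[off::stride, off::stride].ravel())


def detect(models: GanModels, x: ImageSample, config: InversionConfig) -> DetectionResult:
    """Invert, then decide ID/OOD by the K–S p-value at level alpha.

    The K–S statistic compares pixel values of the final reconstruction
    against those of the target, taken on a deterministic spatial subsample
    of stride ``ks_stride`` in each axis (default 4): neighbouring pixels
    are strongly correlated, so spacing the samples keeps the test's
    effective sample size honest; ks_stride=1 uses every pixel.  If the
    loss threshold was never reached the sample is OOD by fiat
    (failure_mode records the route); the K–S result is still computed for
    diagnostics.
    """
    inv = invert(models, x, config)
    recon = generate(models, inv.z_final)
    ks = _pixel_ks(recon.pixels, x.pixels, config.ks_stride)
    loss = reconstruction_loss(models, inv.z_final, x)
    if not inv.reached_threshold:
        return DetectionResult(True, ks, loss, FailureMode.THRESHOLD_NOT_REACHED, inv)
    return DetectionResult(bool(ks.p_value < config.alpha), ks, loss, FailureMode.NONE, inv)


# ---------------------------------------------------------------------------
# Batched trajectories (exact caching for threshold sweeps)
# ---------------------------------------------------------------------------

@dataclass
class LatentTrajectory:
    """Full optimization history of one target image.

    Because the stopping threshold only decides *where* the trajectory is
    cut (the update sequence itself never depends on tau), a single run to
    max_steps can be re-read under any (tau, extra_steps) pair without
    changing results — ``losses[t]`` and ``z_history[t]`` describe the
    iterate before update t, exactly as in :func:`invert`.
    """

    losses: np.ndarray      # (max_steps,)
    z_history: np.ndarray   # (max_steps, latent_dim)

    def stop_index(self, tau: float, extra_steps: int) -> tuple[int, bool, int | None]:
        """(index of the returned iterate, reached_threshold, first-hit step)."""
        hits = np.nonzero(self.losses <= tau)[0]
        if hits.size == 0:
            return len(self.losses) - 1, False, None
        s = int(hits[0])
        return min(s + extra_steps, len(self.losses) - 1), True, s


def invert_trajectories(models: GanModels, images: list[ImageSample],
                        config: InversionConfig) -> list[LatentTrajectory]:
    """Run all latent optimizations jointly for max_steps (one per image).

    Evaluation-mode batchnorm makes samples independent, and Adam is
    elementwise, so the batched run is step-for-step identical to inverting
    each image alone; restarts follow the same lowest-final-loss rule.
    """
    config.validate()
    n = len(images)
    if n == 0:
        return []
    latent = models.config.latent_dim
    xb = np.stack([s.validate().pixels for s in images]).astype(nn.DTYPE)[:, None]
    npix = xb[0].size
    best: list[LatentTrajectory | None] = [None] * n
    for r in range(config.restarts):
        z = np.stack([_restart_latent(config, latent, r) for _ in range(n)])
        opt = nn.Adam([z], config.learning_rate, 0.9, 0.999)
        losses = np.empty((config.max_steps, n))
        z_hist = np.empty((config.max_steps, n, latent), dtype=nn.DTYPE)
        for t in range(config.max_steps):
            img = generator_forward(models, z, train=False)
            diff = img - xb
            step_loss = np.mean(diff.astype(np.float64) ** 2, axis=(1, 2, 3))
            if not np.all(np.isfinite(step_loss)):
                raise TrainingDivergenceError(t, "inversion loss")
            losses[t] = step_loss
            z_hist[t] = z
            if t == config.max_steps - 1:
                break
            dz = generator_backward_to_z(models, (2.0 / npix) * diff)
            opt.step([dz])
        for i in range(n):
            cand = LatentTrajectory(losses[:, i].copy(), z_hist[:, i].copy())
            if best[i] is None or cand.losses[-1] < best[i].losses[-1]:
                best[i] = cand
    return best


def detect_from_trajectory(models: GanModels, x: ImageSample, traj: LatentTrajectory,
                           config: InversionConfig) -> DetectionResult:
    """Apply the stopping rule and K–S decision to a precomputed trajectory."""
    idx, reached, s = traj.stop_index(config.loss_threshold, config.extra_steps)
    z_final = traj.z_history[idx]
    recon = generate(models, z_final)
    ks = _pixel_ks(recon.pixels, x.pixels, config.ks_stride)
    loss = reconstruction_loss(models, z_final, x)
    inv = InversionResult(z_final=z_final.copy(), loss_trace=list(traj.losses[:idx + 1]),
                          reached_threshold=reached, steps_to_threshold=s,
                          total_steps=idx + 1)
    if not reached:
        return DetectionResult(True, ks, loss, FailureMode.THRESHOLD_NOT_REACHED, inv)
    return DetectionResult(bool(ks.p_value < config.alpha), ks, loss, FailureMode.NONE, inv)
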