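"""Procedural chest-phantom generator: two visually distinct grayscale families.

Real chest radiographs come in two acquisition views.  A frontal
(posterior-anterior) projection is roughly left-right symmetric: two dark,
air-filled lung fields flank a bright central mediastinal band.  A lateral
(side-on) projection is strongly asymmetric: the superimposed lungs form
one dominant dark lobe with the bright spinal column off to one side.
This module renders smooth analytic phantoms with exactly those gross
layouts so that view-discrimination pipelines can be trained and evaluated
without any access to clinical data.

Phantoms are built from separable Gaussian / super-Gaussian primitives on
a [-1, 1]^2 coordinate grid, with geometry optionally perturbed per sample
("jitter", emulating patient-to-patient anatomical variability) and
additive Gaussian pixel noise (emulating detector noise).  All intensities
live in the closed interval [-1, 1], the Tanh output range of the
companion generator network.

The frontal template is constructed to be *exactly* mirror symmetric when
jitter and noise are zero: the coordinate grid is antisymmetric in floating
point and every frontal primitive is an even function of the horizontal
coordinate or comes in an exactly mirrored pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


class ViewLabel(enum.Enum):
    FRONTAL = "frontal"
    LATERAL = "lateral"
    UNKNOWN = "unknown"


@dataclass
class ImageSample:
    """One grayscale image on the internal [-1, 1] intensity scale."""

    pixels: np.ndarray
    label: ViewLabel = ViewLabel.UNKNOWN

    def validate(self) -> "ImageSample":
        p = self.pixels
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValidationError(f"pixels: expected square 2-D array, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValidationError("pixels: non-finite values")
        if p.min() < -1.0 or p.max() > 1.0:
            raise ValidationError("pixels: values outside [-1, 1]")
        return self

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PhantomSpec:
    """Parameters of one procedural phantom.

    noise_sigma is the std of additive Gaussian pixel noise on the [-1, 1]
    intensity scale; jitter is the fractional magnitude of random geometry
    perturbations (0 = the fixed class template).
    """

    view_class: ViewLabel
    resolution: int = 64
    noise_sigma: float = 0.02
    jitter: float = 0.10
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.view_class not in (ViewLabel.FRONTAL, ViewLabel.LATERAL):
            raise ValidationError(f"view_class: must be FRONTAL or LATERAL, got {self.view_class}")
        if not isinstance(self.resolution, (int, np.integer)) or self.resolution < 16 \
                or self.resolution % 16 != 0:
            raise ValidationError(f"resolution: must be an integer >= 16 and a multiple of 16, "
                                  f"got {self.resolution}")
        if not 0.0 <= self.noise_sigma <= 0.5:
            raise ValidationError(f"noise_sigma: must be in [0, 0.5], got {self.noise_sigma}")
        if not 0.0 <= self.jitter <= 0.5:
            raise ValidationError(f"jitter: must be in [0, 0.5], got {self.jitter}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError(f"seed: must be an integer, got {type(self.seed).__name__}")
        return self


def _grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate grid on [-1, 1]; exactly antisymmetric: ax[n-1-i] == -ax[i]."""
    ax = (2.0 * np.arange(n) - (n - 1)) / (n - 1)
    u = ax[None, :]  # horizontal (left-right)
    v = ax[:, None]  # vertical (head-foot)
    return u, v


def _lobe(u, v, cu, cv, wu, wv):
    """Elliptical Gaussian lobe centred at (cu, cv)."""
    return np.exp(-(((u - cu) / wu) ** 2 + ((v - cv) / wv) ** 2))


def _frontal(u, v, rng: np.random.Generator, jitter: float) -> np.ndarray:
    # independent perturbations for the two lung fields break symmetry
    # smoothly as jitter grows
    d = jitter * rng.uniform(-1.0, 1.0, size=8)
    cl, cr = -0.40 + 0.25 * d[0], 0.40 + 0.25 * d[1]
    wl, wr = 0.28 * (1 + 0.5 * d[2]), 0.28 * (1 + 0.5 * d[3])
    hl, hr = 0.50 * (1 + 0.4 * d[4]), 0.50 * (1 + 0.4 * d[5])
    band_w = 0.18 * (1 + 0.5 * d[6])
    amp = 1 + 0.15 * d[7]
    # smooth radial falloff instead of a flat field: radiographs have no
    # exactly constant regions, and the pixel-distribution test presumes
    # a spread-out intensity histogram
    img = 0.15 - 0.85 * (u * u + v * v) / 2.0
    img += 0.55 * np.exp(-((u / 0.62) ** 2 + (v / 0.80) ** 2) ** 2)          # torso
    img += 0.55 * np.exp(-((u / band_w) ** 2)) * np.exp(-((v / 0.85) ** 2))  # mediastinum
    # single commutative sum keeps the jitter-free template exactly symmetric
    lungs = _lobe(u, v, cl, 0.05, wl, hl) + _lobe(u, v, cr, 0.05, wr, hr)
    img -= 0.65 * amp * lungs
    img += 0.30 * np.exp(-(((v + 0.78) / 0.28) ** 2))                        # shoulder girdle
    return img


def _lateral(u, v, rng: np.random.Generator, jitter: float) -> np.ndarray:
    d = jitter * rng.uniform(-1.0, 1.0, size=8)
    lobe_cu = -0.18 + 0.25 * d[0]
    lobe_wu = 0.40 * (1 + 0.4 * d[1])
    lobe_wv = 0.54 * (1 + 0.4 * d[2])
    spine_cu = 0.50 + 0.20 * d[3]
    spine_w = 0.16 * (1 + 0.5 * d[4])
    dia_cv = 0.60 + 0.15 * d[5]
    amp = 1 + 0.15 * d[6]
    torso_cu = 0.05 + 0.1 * d[7]
    # decentred smooth falloff (stronger toward the posterior edge)
    img = 0.15 - 0.80 * ((u - 0.10) ** 2 + v * v) / 2.0 - 0.15 * u
    img += 0.55 * np.exp(-((((u - torso_cu) / 0.68) ** 2 + (v / 0.82) ** 2) ** 2))  # torso
    img += 0.50 * np.exp(-(((u - spine_cu) / spine_w) ** 2)) * np.exp(-((v / 0.90) ** 2))  # spine
    img -= 0.70 * amp * _lobe(u, v, lobe_cu, 0.02, lobe_wu, lobe_wv)  # superimposed lungs
    img += 0.35 * np.exp(-(((v - dia_cv) / 0.24) ** 2)) / (1.0 + np.exp(4.0 * (u - 0.30)))  # diaphragm
    img += 0.25 * np.exp(-(((v + 0.80) / 0.28) ** 2))  # shoulders
    return img


def generate_phantom(spec: PhantomSpec) -> ImageSample:
    """Render one phantom; fully deterministic given the spec fields."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed % (2 ** 63)))
    u, v = _grid(spec.resolution)
    if spec.view_class is ViewLabel.FRONTAL:
        img = _frontal(u, v, rng, spec.jitter)
    else:
        img = _lateral(u, v, rng, spec.jitter)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    np.clip(img, -1.0, 1.0, out=img)
    return ImageSample(pixels=img, label=spec.view_class).validate()


def _child_seed(master_seed: int, index: int) -> int:
    """Counter-based per-sample seed derivation (documented, deterministic)."""
    ss = np.random.SeedSequence(master_seed % (2 ** 63), spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_dataset(n_frontal: int, n_lateral: int, base_spec: PhantomSpec,
                     seed: int) -> list[ImageSample]:
    """n_frontal FRONTAL then n_lateral LATERAL phantoms, element-wise reproducible.

    Per-sample seeds are derived from ``seed`` by a counter-based spawn, so
    sample i is identical across runs and independent of the total counts.
    """
    if n_frontal < 0 or n_lateral < 0:
        raise ValidationError("n_frontal/n_lateral: must be >= 0")
    base_spec.validate()
    samples = []
    views = [ViewLabel.FRONTAL] * n_frontal + [ViewLabel.LATERAL] * n_lateral
    for i, view in enumerate(views):
        spec = PhantomSpec(view_class=view, resolution=base_spec.resolution,
                           noise_sigma=base_spec.noise_sigma, jitter=base_spec.jitter,
                           seed=_child_seed(seed, i))
        samples.append(generate_phantom(spec))
    return samples
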