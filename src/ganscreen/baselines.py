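"""Classical view-discrimination baselines: Canny edge score and histogram score.

Both reduce an image to a single scalar that is thresholded to call
OOD, with the threshold chosen by an F1-maximizing grid search on a
labeled calibration split.

* ``canny_score``: fraction of pixels the classical Canny operator
  (Gaussian smoothing, gradient, non-maximum suppression, hysteresis)
  marks as edges.  Lateral views project more overlapping structure, so
  the edge fraction shifts between views; the OOD side of the threshold
  is a free parameter of the grid search.
* ``histogram_score``: histogram intersection between the image's
  normalized intensity histogram and a reference histogram averaged over
  in-distribution images — 1.0 means identical histograms, so *low*
  scores are OOD-like (ood_side BELOW).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from skimage import feature as _skfeature

from .errors import ValidationError
from .synthetic import ImageSample


class OodSide(enum.Enum):
    ABOVE = "above"
    BELOW = "below"


@dataclass(frozen=True)
class ReferenceHistogram:
    bin_edges: np.ndarray     # len n_bins + 1, partitioning [-1, 1]
    mean_density: np.ndarray  # len n_bins, sums to 1

    def validate(self) -> "ReferenceHistogram":
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValidationError("bin_edges: must be strictly increasing")
        if abs(float(self.mean_density.sum()) - 1.0) > 1e-12:
            raise ValidationError("mean_density: must sum to 1")
        return self


@dataclass(frozen=True)
class BaselineScore:
    method: str            # "canny" | "histogram"
    score: float
    threshold: float
    predicted_ood: bool


def canny_score(image: ImageSample, sigma: float = 1.0,
                low: float = 0.1, high: float = 0.2) -> float:
    """Edge-pixel fraction of the full Canny operator, in [0, 1].

    ``low``/``high`` are hysteresis thresholds on the gradient magnitude of
    the [0, 1]-rescaled image; a constant image scores 0.
    """
    if not low < high:
        raise ValidationError(f"thresholds: need low < high, got {low} >= {high}")
    image.validate()
    img01 = (image.pixels + 1.0) / 2.0
    edges = _skfeature.canny(img01, sigma=sigma, low_threshold=low, high_threshold=high)
    return float(edges.mean())


def fit_reference_histogram(id_images: list[ImageSample], n_bins: int = 32) -> ReferenceHistogram:
    """Mean of per-image normalized histograms over equal-width bins on [-1, 1]."""
    if not id_images:
        raise ValidationError("id_images: must be non-empty")
    if n_bins < 1:
        raise ValidationError(f"n_bins: must be positive, got {n_bins}")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    densities = []
    for s in id_images:
        h, _ = np.histogram(s.validate().pixels, bins=edges)
        densities.append(h / h.sum())
    mean = np.mean(densities, axis=0)
    mean = mean / mean.sum()  # guard against accumulated rounding
    return ReferenceHistogram(bin_edges=edges, mean_density=mean).validate()


def histogram_score(image: ImageSample, ref: ReferenceHistogram) -> float:
    """Histogram intersection sum(min(h_image, h_ref)) in [0, 1]; higher = ID-like."""
    ref.validate()
    h, _ = np.histogram(image.validate().pixels, bins=ref.bin_edges)
    h = h / h.sum()
    return float(np.minimum(h, ref.mean_density).sum())


def _f1_counts(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """(f1, precision) with the 0-denominator convention."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return f1, precision


def grid_search_threshold(scores, labels, grid, ood_side: OodSide) -> tuple[float, float]:
    """Grid value maximizing F1 of the OOD-positive call.

    ``labels`` are booleans (True = OOD).  Ties prefer higher precision,
    then the smaller threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    grid = list(grid)
    if scores.shape != labels.shape:
        raise ValidationError("scores/labels: length mismatch")
    if not grid:
        raise ValidationError("grid: must be non-empty")
    if labels.all() or not labels.any():
        raise ValidationError("labels: both classes must be present")
    best = None
    for thr in sorted(grid):
        pred = scores > thr if ood_side is OodSide.ABOVE else scores < thr
        tp = int(np.sum(pred & labels))
        fp = int(np.sum(pred & ~labels))
        fn = int(np.sum(~pred & labels))
        f1, prec = _f1_counts(tp, fp, fn)
        key = (f1, prec, -thr)  # later comparison keeps the smaller thr on ties
        if best is None or key > best[0]:
            best = (key, thr, f1)
    return best[1], best[2]


def score_images(images: list[ImageSample], method: str, *,
                 ref: ReferenceHistogram | None = None,
                 sigma: float = 1.0, low: float = 0.1, high: float = 0.2) -> np.ndarray:
    """Convenience vectorizer for either baseline score."""
    if method == "canny":
        return np.array([canny_score(s, sigma, low, high) for s in images])
    if method == "histogram":
        if ref is None:
            raise ValidationError("ref: required for the histogram method")
        return np.array([histogram_score(s, ref) for s in images])
    raise ValidationError(f"method: unknown baseline {method!r}")
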