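"""Pixel-based grape segmentation.

Five two-class pixel classifiers, all trained from small circular templates
selected on a reference image:

* layer thresholding with the threshold fixed by Otsu's method,
* nearest-class Mahalanobis distance between two Gaussian color models,
* a quadratic Gaussian (Bayes) discriminant with unequal covariances and
  class priors,
* linear color models (LCM): minimum point-to-line distance in color space,
* occupancy lookup in a 3-D color histogram dilated by a solid sphere.

Every classifier maps a :class:`~nightgrape.colorspace.ColorImage` to a
boolean mask (``True`` = grape).  Ties are always resolved in favor of the
background class, which is conservative for yield estimation.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .colorspace import HSV_SHIFTED, RGB, ColorImage, IntensityLayer

__all__ = [
    "DegenerateInputError",
    "TemplateSelection",
    "PixelSample",
    "GaussianColorModel",
    "LineColorModel",
    "ColorHistogram3D",
    "ThresholdRule",
    "GRAPE_PRIOR",
    "BACKGROUND_PRIOR",
    "sample_template",
    "otsu_threshold",
    "train_threshold_rule",
    "threshold_segment",
    "fit_gaussian_model",
    "mahalanobis_segment",
    "bayes_segment",
    "fit_line_model",
    "lcm_segment",
    "build_dilated_histogram",
    "histogram_segment",
    "save_models",
    "load_models",
]

#: Class prior probabilities tuned for reddish table grapes under night
#: flash illumination: grape pixels are the minority class.
GRAPE_PRIOR = 0.4336
BACKGROUND_PRIOR = 0.5664

#: Diagonal regularization added to sample covariances so that nearly
#: uniform templates still yield an invertible model.
COV_EPSILON = 1e-6


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. a constant layer)."""


@dataclass
class TemplateSelection:
    """A circular manual selection: center (row, col), radius, class label."""

    center: tuple[int, int]
    radius: float
    label: str = "grape"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("template radius must be >= 1 pixel")


@dataclass
class PixelSample:
    """N×3 template pixel colors plus the color space they came from."""

    colors: np.ndarray
    source_space: str = RGB

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=float)
        if self.colors.ndim != 2 or self.colors.shape[1] != 3:
            raise ValueError("colors must be N×3")

    def __len__(self) -> int:
        return self.colors.shape[0]


def sample_template(img: ColorImage, sel: TemplateSelection) -> PixelSample:
    """Collect the colors of all pixels whose center lies inside the circle."""
    h, w = img.shape
    cy, cx = sel.center
    r = sel.radius
    if cy - r < -0.5 or cx - r < -0.5 or cy + r > h - 0.5 or cx + r > w - 0.5:
        raise ValueError("template circle extends outside the image")
    r0, r1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    c0, c1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    yy, xx = np.mgrid[r0 : min(r1, h), c0 : min(c1, w)]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return PixelSample(img.pixels[r0 : min(r1, h), c0 : min(c1, w)][inside], img.space)


def pool_samples(samples: list[PixelSample]) -> PixelSample:
    """Concatenate several template samples from the same color space."""
    spaces = {s.source_space for s in samples}
    if len(spaces) != 1:
        raise ValueError("cannot pool samples from different color spaces")
    return PixelSample(np.vstack([s.colors for s in samples]), spaces.pop())


# ---------------------------------------------------------------------------
# Threshold segmentation
# ---------------------------------------------------------------------------

@dataclass
class ThresholdRule:
    """Keep-above threshold on one intensity layer; value on the [0, 1] scale."""

    layer: str
    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def _quantize_255(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values * 255.0), 0, 255).astype(np.intp)


def otsu_threshold(layer: IntensityLayer) -> float:
    """Otsu's threshold over a 256-level histogram of the layer.

    Intensities are quantized to the 8-bit levels ``0..255``; the returned
    threshold is ``k / 255`` for the level ``k`` maximizing the between-class
    variance of the split ``{levels <= k}`` versus ``{levels > k}``.  With a
    keep-above rule the foreground is the bright class.
    """
    levels = _quantize_255(layer.values)
    hist = np.bincount(levels.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("layer is constant; Otsu threshold undefined")
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # mass of the low class
    mu = np.cumsum(p * np.arange(256))        # partial first moment
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))
    return k / 255.0


def train_threshold_rule(layer: IntensityLayer) -> ThresholdRule:
    """Fix a keep-above threshold rule for a layer by Otsu's method."""
    return ThresholdRule(layer=layer.layer, threshold=otsu_threshold(layer))


def threshold_segment(layer: IntensityLayer, rule: ThresholdRule) -> np.ndarray:
    """Binary mask, true exactly where the layer value strictly exceeds the
    threshold (a value equal to the threshold is background)."""
    if rule.layer != layer.layer:
        raise ValueError(
            f"rule is for layer {rule.layer!r} but got layer {layer.layer!r}"
        )
    return layer.values > rule.threshold


# ---------------------------------------------------------------------------
# Gaussian color models: Mahalanobis and Bayes classifiers
# ---------------------------------------------------------------------------

@dataclass
class GaussianColorModel:
    """Gaussian description of a template class in 3-D color space."""

    mean: np.ndarray
    covariance: np.ndarray
    prior: float = 0.5
    space: str = RGB

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(3, 3)
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive definite")
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie in (0, 1)")
        self._inv = np.linalg.inv(self.covariance)
        sign, logdet = np.linalg.slogdet(self.covariance)
        self._logdet = logdet

    def mahalanobis_sq(self, colors: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each N×3 color to the model."""
        d = np.asarray(colors, dtype=float) - self.mean
        return np.einsum("...i,ij,...j->...", d, self._inv, d)

    def log_discriminant(self, colors: np.ndarray) -> np.ndarray:
        """Quadratic Gaussian discriminant g(x) = -½ln|Σ| - ½d²(x) + ln p."""
        return (
            -0.5 * self._logdet
            - 0.5 * self.mahalanobis_sq(colors)
            + np.log(self.prior)
        )


def fit_gaussian_model(
    sample: PixelSample, prior: float = 0.5, epsilon: float = COV_EPSILON
) -> GaussianColorModel:
    """Sample mean and (regularized) covariance of a template sample."""
    if len(sample) < 4:
        raise ValueError("need at least 4 template pixels to fit a Gaussian")
    mean = sample.colors.mean(axis=0)
    cov = np.cov(sample.colors, rowvar=False) + epsilon * np.eye(3)
    return GaussianColorModel(mean, cov, prior=prior, space=sample.source_space)


def _check_model_space(img: ColorImage, *models) -> None:
    for m in models:
        if m.space != img.space:
            raise ValueError(
                f"model trained in {m.space!r} applied to a {img.space!r} image"
            )


def mahalanobis_segment(
    img: ColorImage, grape: GaussianColorModel, bg: GaussianColorModel
) -> np.ndarray:
    """Nearest-class rule on Mahalanobis distance; ties go to background."""
    _check_model_space(img, grape, bg)
    return grape.mahalanobis_sq(img.pixels) < bg.mahalanobis_sq(img.pixels)


def bayes_segment(
    img: ColorImage, grape: GaussianColorModel, bg: GaussianColorModel
) -> np.ndarray:
    """Quadratic Gaussian discriminant with class priors; ties to background.

    Assumes unequal class covariances and correlated color features, so the
    full quadratic form is kept rather than a naive (diagonal) reduction.
    """
    _check_model_space(img, grape, bg)
    if abs(grape.prior + bg.prior - 1.0) > 1e-9:
        raise ValueError("class priors must sum to 1")
    return grape.log_discriminant(img.pixels) > bg.log_discriminant(img.pixels)


# ---------------------------------------------------------------------------
# Linear color models (LCM)
# ---------------------------------------------------------------------------

@dataclass
class LineColorModel:
    """A line in 3-D color space: centroid point plus unit direction."""

    point: np.ndarray
    direction: np.ndarray
    label: str = "grape"
    space: str = RGB

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.direction = self.direction / n

    def distance_sq(self, colors: np.ndarray) -> np.ndarray:
        d = np.asarray(colors, dtype=float) - self.point
        t = d @ self.direction
        return np.maximum(np.einsum("...i,...i->...", d, d) - t * t, 0.0)


def fit_line_model(sample: PixelSample, label: str = "grape") -> LineColorModel:
    """Total-least-squares line through a template sample.

    The line passes through the sample centroid along the first principal
    direction; this is symmetric in the three color channels, matching the
    point-to-line distance used for classification.  The direction sign is
    canonicalized (first nonzero component positive) for determinism.
    """
    if len(sample) < 4:
        raise ValueError("need at least 4 template pixels to fit a line")
    centered = sample.colors - sample.colors.mean(axis=0)
    if np.abs(centered).max() < 1e-12:
        raise DegenerateInputError("zero-variance sample cannot define a line")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    nz = np.flatnonzero(np.abs(direction) > 1e-12)
    if direction[nz[0]] < 0:
        direction = -direction
    return LineColorModel(
        sample.colors.mean(axis=0), direction, label=label, space=sample.source_space
    )


def lcm_segment(
    img: ColorImage,
    grape_lines: list[LineColorModel],
    bg_lines: list[LineColorModel],
) -> np.ndarray:
    """Minimum point-to-line distance over each class's line set; ties to
    background."""
    if not grape_lines or not bg_lines:
        raise ValueError("each class needs at least one line model")
    _check_model_space(img, *grape_lines, *bg_lines)
    d_grape = np.min([ln.distance_sq(img.pixels) for ln in grape_lines], axis=0)
    d_bg = np.min([ln.distance_sq(img.pixels) for ln in bg_lines], axis=0)
    return d_grape < d_bg


# ---------------------------------------------------------------------------
# 3-D color-histogram segmentation
# ---------------------------------------------------------------------------

@dataclass
class ColorHistogram3D:
    """Boolean occupancy over a B×B×B quantization of color space."""

    bins: int
    occupancy: np.ndarray
    dilation_radius: int = 0
    space: str = RGB

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("need at least 2 bins per layer")
        if self.dilation_radius < 0:
            raise ValueError("dilation radius must be >= 0")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != (self.bins,) * 3:
            raise ValueError("occupancy must be bins³")
        if not self.occupancy.any():
            raise ValueError("histogram occupancy is empty")

    def bin_indices(self, colors: np.ndarray) -> np.ndarray:
        """Half-open quantization: floor(value·B), clamped to B−1 at 1.0."""
        idx = np.floor(np.asarray(colors, dtype=float) * self.bins).astype(np.intp)
        return np.clip(idx, 0, self.bins - 1)


def build_dilated_histogram(
    sample: PixelSample, bins: int = 128, radius: int = 6
) -> ColorHistogram3D:
    """Occupancy histogram of a grape template, dilated by a solid sphere.

    The dilation by the discrete Euclidean ball of the given radius (offsets
    with norm <= radius, clipped at the histogram edges) fills gaps in the
    sampled color relationship; segmentation then tests occupancy, i.e. a
    zero threshold on the dilated histogram.  Implemented via the Euclidean
    distance transform of the unoccupied bins, which is exactly the ball
    dilation but cheaper than an explicit convolution.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins per layer")
    if radius < 0:
        raise ValueError("dilation radius must be >= 0")
    occ = np.zeros((bins,) * 3, dtype=bool)
    idx = np.clip(
        np.floor(sample.colors * bins).astype(np.intp), 0, bins - 1
    )
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if radius > 0:
        dist = ndimage.distance_transform_edt(~occ)
        occ = dist <= radius
    return ColorHistogram3D(bins, occ, dilation_radius=radius, space=sample.source_space)


def histogram_segment(img: ColorImage, hist: ColorHistogram3D) -> np.ndarray:
    """Grape wherever the pixel's quantized color bin is occupied."""
    if img.space != hist.space:
        raise ValueError(
            f"histogram trained in {hist.space!r} applied to a {img.space!r} image"
        )
    idx = hist.bin_indices(img.pixels)
    return hist.occupancy[idx[..., 0], idx[..., 1], idx[..., 2]]


# ---------------------------------------------------------------------------
# Model serialization (portable JSON, reused across a batch)
# ---------------------------------------------------------------------------

def _model_to_dict(model) -> dict:
    if isinstance(model, ThresholdRule):
        return {"kind": "threshold", "layer": model.layer, "threshold": model.threshold}
    if isinstance(model, GaussianColorModel):
        return {
            "kind": "gaussian",
            "mean": model.mean.tolist(),
            "covariance": model.covariance.tolist(),
            "prior": model.prior,
            "space": model.space,
        }
    if isinstance(model, LineColorModel):
        return {
            "kind": "line",
            "point": model.point.tolist(),
            "direction": model.direction.tolist(),
            "label": model.label,
            "space": model.space,
        }
    if isinstance(model, ColorHistogram3D):
        packed = np.packbits(model.occupancy.ravel())
        return {
            "kind": "histogram",
            "bins": model.bins,
            "dilation_radius": model.dilation_radius,
            "space": model.space,
            "occupancy_bits": base64.b64encode(packed.tobytes()).decode("ascii"),
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def _model_from_dict(d: dict):
    kind = d["kind"]
    if kind == "threshold":
        return ThresholdRule(layer=d["layer"], threshold=d["threshold"])
    if kind == "gaussian":
        return GaussianColorModel(
            d["mean"], d["covariance"], prior=d["prior"], space=d["space"]
        )
    if kind == "line":
        return LineColorModel(
            d["point"], d["direction"], label=d["label"], space=d["space"]
        )
    if kind == "histogram":
        b = d["bins"]
        bits = np.frombuffer(base64.b64decode(d["occupancy_bits"]), dtype=np.uint8)
        occ = np.unpackbits(bits)[: b**3].reshape((b,) * 3).astype(bool)
        return ColorHistogram3D(
            b, occ, dilation_radius=d["dilation_radius"], space=d["space"]
        )
    raise ValueError(f"unknown model kind {kind!r}")


def save_models(path, models: dict) -> None:
    """Write a name → trained-model mapping to a portable JSON file."""
    payload = {name: _model_to_dict(m) for name, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_models(path) -> dict:
    """Read back a mapping written by :func:`save_models`."""
    with open(path) as fh:
        payload = json.load(fh)
    return {name: _model_from_dict(d) for name, d in payload.items()}
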