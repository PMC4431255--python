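"""Color layer extraction and the shifted-hue transform.

Red grape skin sits at the 0/1 wrap-around of the hue circle, which makes
single-threshold segmentation on raw hue impossible.  Rotating hue by 180°
moves red to the center of the unit interval, so a reddish class becomes a
contiguous band that one threshold can isolate.  All intensities are kept as
floats in [0, 1]; 8-bit thresholds printed on a 0–255 scale correspond to
``level / 255`` here.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

__all__ = [
    "RGB",
    "HSV_SHIFTED",
    "LAYER_TAGS",
    "ColorImage",
    "IntensityLayer",
    "rgb_to_hsv_shifted",
    "hsv_shifted_to_rgb",
    "extract_layer",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
]

RGB = "RGB"
HSV_SHIFTED = "HSV-shifted"

#: BT.601 luma weights used for the gray (I) layer.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Valid layer tags and the color space each one lives in.
LAYER_TAGS = {
    "R": RGB,
    "G": RGB,
    "B": RGB,
    "I": RGB,
    "H": HSV_SHIFTED,
    "S": HSV_SHIFTED,
    "V": HSV_SHIFTED,
}


@dataclass
class ColorImage:
    """An H×W×3 float image with intensities in [0, 1] and a space tag.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3)
        Per-pixel intensities in [0, 1].
    space : str
        Either ``"RGB"`` or ``"HSV-shifted"`` (hue rotated by 180°).
    """

    pixels: np.ndarray
    space: str = RGB

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if self.space not in (RGB, HSV_SHIFTED):
            raise ValueError(f"unknown color space {self.space!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class IntensityLayer:
    """A single H×W channel in [0, 1] with its layer tag."""

    values: np.ndarray
    layer: str = "I"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be 2-D")
        if self.layer not in LAYER_TAGS:
            raise ValueError(f"unknown layer tag {self.layer!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rgb_to_hsv_shifted(img: ColorImage) -> ColorImage:
    """Convert RGB to HSV with the hue plane rotated by 180°.

    Hue is normalized to [0, 1]; the rotation is ``H' = (H + 0.5) mod 1`` so
    pure red maps to 0.5.  Achromatic pixels (S = 0) take raw hue 0 and hence
    shifted hue 0.5.  Saturation and value are unchanged.
    """
    if img.space != RGB:
        raise ValueError(f"expected an RGB image, got space={img.space!r}")
    hsv = _skcolor.rgb2hsv(img.pixels)
    hsv[..., 0] = (hsv[..., 0] + 0.5) % 1.0
    return ColorImage(hsv, space=HSV_SHIFTED)


def hsv_shifted_to_rgb(img: ColorImage) -> ColorImage:
    """Invert :func:`rgb_to_hsv_shifted` (exact for saturated pixels)."""
    if img.space != HSV_SHIFTED:
        raise ValueError(f"expected an HSV-shifted image, got space={img.space!r}")
    hsv = img.pixels.copy()
    hsv[..., 0] = (hsv[..., 0] - 0.5) % 1.0
    rgb = np.clip(_skcolor.hsv2rgb(hsv), 0.0, 1.0)
    return ColorImage(rgb, space=RGB)


def extract_layer(img: ColorImage, layer: str) -> IntensityLayer:
    """Pull one named channel out of a color image.

    ``R``/``G``/``B`` and the gray layer ``I`` (BT.601 luma) require an RGB
    image; ``H``/``S``/``V`` require an HSV-shifted image.
    """
    if layer not in LAYER_TAGS:
        raise ValueError(f"unknown layer tag {layer!r}")
    required = LAYER_TAGS[layer]
    if img.space != required:
        raise ValueError(
            f"layer {layer!r} requires a {required} image, got {img.space!r}"
        )
    if layer == "I":
        values = img.pixels @ _LUMA
    else:
        idx = {"R": 0, "G": 1, "B": 2, "H": 0, "S": 1, "V": 2}[layer]
        values = img.pixels[..., idx]
    return IntensityLayer(np.clip(values, 0.0, 1.0), layer=layer)


def load_image(path) -> ColorImage:
    """Read a PNG/TIFF/JPEG image as an RGB ColorImage in [0, 1].

    8-bit inputs are divided by 255, 16-bit by 65535; float inputs are
    clipped to [0, 1].  Grayscale inputs are broadcast to three channels and
    an alpha channel, if present, is dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        pixels = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(float) / 65535.0
    else:
        pixels = np.clip(arr.astype(float), 0.0, 1.0)
    return ColorImage(pixels, space=RGB)


def save_image(path, img: ColorImage) -> None:
    """Write a ColorImage as an 8-bit RGB file (RGB images only)."""
    if img.space != RGB:
        raise ValueError("only RGB images can be written")
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_mask(path) -> np.ndarray:
    """Read a binary mask PNG (any nonzero pixel is foreground)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr > 0


def save_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = foreground)."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
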