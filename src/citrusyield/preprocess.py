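"""Contrast enhancement and color-space conversion.

The processing chain applied before segmentation is deliberately minimal:
global per-channel histogram equalization on the RGB image, then conversion
to HSV with every channel on the 0-255 scale.  The published citrus
thresholds (19, 39, 31, 243, 221, 255) are 8-bit values; converting hue to
[0, 360) or 179 (the OpenCV convention) silently breaks them, so the 0-255
scaling is enforced here and tagged on the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

from .errors import ColorSpaceError, FormatError

__all__ = ["RasterImage", "equalize_histogram", "rgb_to_hsv_255", "hsv_255_to_rgb"]


@dataclass
class RasterImage:
    """An 8-bit H x W x 3 raster with an explicit color-space tag."""

    pixels: np.ndarray
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected H x W x 3 image, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise FormatError(f"expected 8-bit (uint8) image, got dtype {px.dtype}")
        if self.color_space not in ("RGB", "HSV"):
            raise FormatError(f"unknown color space {self.color_space!r}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def _require(image: RasterImage, space: str) -> np.ndarray:
    if not isinstance(image, RasterImage):
        image = RasterImage(np.asarray(image), space)
    if image.color_space != space:
        raise ColorSpaceError(
            f"expected a {space} image, got {image.color_space}")
    return image.pixels


def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    """Map one uint8 channel through its cumulative histogram.

    The classic lookup ``lut(v) = round(255 * (cdf(v) - cdf_min) / (n - cdf_min))``
    over 256 bins: an already-uniform histogram maps to the identity, and the
    mapping is monotone non-decreasing, so pixel rank order is preserved.  A
    constant channel (cdf_min == n) is returned unchanged.
    """
    hist = np.bincount(channel.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = cdf[-1]
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if n == cdf_min:  # single occupied bin
        return channel.copy()
    lut = np.floor((cdf - cdf_min) / (n - cdf_min) * 255.0 + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[channel]


def equalize_histogram(image: RasterImage) -> RasterImage:
    """Per-channel global histogram equalization of an 8-bit RGB image.

    Each channel is remapped independently by its own 256-bin cumulative
    histogram toward a uniform distribution.  Applied before HSV conversion;
    shape is unchanged.
    """
    px = _require(image, "RGB")
    out = np.stack([_equalize_channel(px[..., c]) for c in range(3)], axis=-1)
    return RasterImage(out, "RGB")


def rgb_to_hsv_255(image: RasterImage) -> RasterImage:
    """Standard hexcone RGB -> HSV with all channels rescaled to [0, 255].

    Hue is the hue fraction (degrees / 360) times 255; gray pixels, whose hue
    is undefined, get hue 0 and saturation 0.
    """
    px = _require(image, "RGB")
    hsv = _skcolor.rgb2hsv(px.astype(np.float64) / 255.0)
    out = np.clip(np.floor(hsv * 255.0 + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(out, "HSV")


def hsv_255_to_rgb(image: RasterImage) -> RasterImage:
    """Inverse of :func:`rgb_to_hsv_255` (exact up to 8-bit quantization)."""
    px = _require(image, "HSV")
    rgb = _skcolor.hsv2rgb(px.astype(np.float64) / 255.0)
    out = np.clip(np.floor(rgb * 255.0 + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(out, "RGB")
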