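"""Tree and fruit segmentation.

Two kinds of per-pixel evidence are combined:

* an axis-aligned box in 8-bit HSV space (the citrus color range), and
* scalar vegetation/fruit indices computed from raw RGB channels:
  ``I_PCA = 0.994|R-B| + 0.961|G-B| + 0.914|B-R|`` (canopy vs ground; note
  the first and third terms are deliberately the same absolute difference,
  implemented verbatim as published), ``CIVE = 0.441R - 0.811G + 0.385B +
  18.78`` (low over vegetation) and ``I1 = R + G - 2B``.

A fruit mask is the intersection of a tree mask (I_PCA + Otsu) with the
fruit-candidate mask of the chosen method; fruit pixels are then counted
inside each tree's crown polygon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu

from .errors import (ColorSpaceError, DegenerateHistogramError,
                     InvalidParameterError)
from .preprocess import RasterImage, rgb_to_hsv_255

__all__ = [
    "HSVRange", "Mask", "TreeROI", "IndexMap",
    "ipca_index", "cive_index", "i1_index",
    "hsv_threshold", "threshold_index", "tree_mask", "fruit_mask",
    "count_pixels",
]

#: Verbatim index weights for |R-B|, |G-B|, |B-R|.
IPCA_WEIGHTS = (0.994, 0.961, 0.914)
CIVE_COEFFS = (0.441, -0.811, 0.385, 18.78)


@dataclass(frozen=True)
class HSVRange:
    """Inclusive per-channel [lo, hi] box on the 0-255 HSV scale.

    Defaults are the published citrus range H in [19, 39], S in [31, 243],
    V in [221, 255].  Hue wrap-around (lo > hi) is not supported: the citrus
    hue band does not cross 0, and a crossing range is rejected.
    """

    h_lo: int = 19
    h_hi: int = 39
    s_lo: int = 31
    s_hi: int = 243
    v_lo: int = 221
    v_hi: int = 255

    def __post_init__(self) -> None:
        for lo, hi, name in ((self.h_lo, self.h_hi, "H"),
                             (self.s_lo, self.s_hi, "S"),
                             (self.v_lo, self.v_hi, "V")):
            if not (0 <= lo <= 255 and 0 <= hi <= 255):
                raise InvalidParameterError(f"{name} bounds must be in [0, 255]")
            if lo > hi:
                raise InvalidParameterError(
                    f"{name} range [{lo}, {hi}] has lo > hi; wrap-around hue "
                    "ranges are not supported")

    @property
    def lows(self) -> tuple[int, int, int]:
        return (self.h_lo, self.s_lo, self.v_lo)

    @property
    def highs(self) -> tuple[int, int, int]:
        return (self.h_hi, self.s_hi, self.v_hi)


@dataclass
class Mask:
    """Boolean raster with the provenance of the rule that produced it."""

    values: np.ndarray
    provenance: str = "hsv"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise InvalidParameterError("mask must be a 2-D boolean raster")

    @property
    def shape(self):
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def intersection(self, other: "Mask") -> "Mask":
        if self.shape != other.shape:
            raise InvalidParameterError("mask shapes differ")
        return Mask(self.values & other.values, "intersection")


@dataclass
class IndexMap:
    """Real-valued per-pixel index raster."""

    values: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("index map contains non-finite values")


@dataclass
class TreeROI:
    """Labeled crown polygon in 0-based pixel coordinates (x right, y down)."""

    label: str
    polygon: np.ndarray  # (N, 2) array of (x, y) vertices

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=np.float64)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise InvalidParameterError(
                f"ROI {self.label!r}: polygon needs >= 3 (x, y) vertices")
        if not Polygon(poly).is_simple:
            raise InvalidParameterError(
                f"ROI {self.label!r}: polygon is self-intersecting")
        self.polygon = poly

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


def _channels(image: RasterImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not isinstance(image, RasterImage):
        image = RasterImage(np.asarray(image), "RGB")
    if image.color_space != "RGB":
        raise ColorSpaceError("index computation expects an RGB image")
    px = image.pixels.astype(np.float64)
    return px[..., 0], px[..., 1], px[..., 2]


def ipca_index(image: RasterImage, variant: str = "verbatim") -> IndexMap:
    """Principal-component-style canopy index on raw channel values.

    ``variant="verbatim"`` evaluates the published weighted sum exactly,
    including the duplicated |R-B| term (so the effective R-B weight is
    0.994 + 0.914).  ``variant="distinct"`` replaces the third term with
    0.914|R-G| for sensitivity studies; it is never the default.
    """
    r, g, b = _channels(image)
    w1, w2, w3 = IPCA_WEIGHTS
    if variant == "verbatim":
        third = np.abs(b - r)
    elif variant == "distinct":
        third = np.abs(r - g)
    else:
        raise InvalidParameterError(f"unknown ipca variant {variant!r}")
    return IndexMap(w1 * np.abs(r - b) + w2 * np.abs(g - b) + w3 * third, "I_PCA")


def cive_index(image: RasterImage) -> IndexMap:
    """Color Index of Vegetation Extraction; low values indicate vegetation."""
    r, g, b = _channels(image)
    cr, cg, cb, c0 = CIVE_COEFFS
    return IndexMap(cr * r + cg * g + cb * b + c0, "CIVE")


def i1_index(image: RasterImage) -> IndexMap:
    """The simple chromatic index R + G - 2B."""
    r, g, b = _channels(image)
    return IndexMap(r + g - 2.0 * b, "I_1")


_INDEX_FUNCS = {"ipca": ipca_index, "cive": cive_index, "i1": i1_index}
#: Foreground polarity putting orange fruit on top *within* the tree mask.
#: Fruit is high for all three: for CIVE the -0.811 G term makes foliage the
#: low class, so relative to canopy the orange fruit sits above the cut.
_FRUIT_POLARITY = {"ipca": "above", "cive": "above", "i1": "above"}


def hsv_threshold(image: RasterImage, hsv_range: HSVRange | None = None) -> Mask:
    """Pixels whose H, S and V all lie inside the inclusive box."""
    if not isinstance(image, RasterImage):
        image = RasterImage(np.asarray(image), "HSV")
    if image.color_space != "HSV":
        raise ColorSpaceError(
            "hsv_threshold expects an HSV image on the 0-255 scale; "
            "convert with rgb_to_hsv_255 first")
    rng = hsv_range if hsv_range is not None else HSVRange()
    px = image.pixels
    lo = np.asarray(rng.lows, dtype=np.uint8)
    hi = np.asarray(rng.highs, dtype=np.uint8)
    ok = np.all((px >= lo) & (px <= hi), axis=-1)
    return Mask(ok, "hsv")


def threshold_index(index_map: IndexMap, strategy: str = "otsu",
                    fixed_value: float | None = None, polarity: str = "above",
                    restrict: np.ndarray | None = None) -> Mask:
    """Binarize an index map.

    ``otsu`` picks the cut maximizing between-class variance of a 256-bin
    histogram over the observed value range (optionally restricted to the
    pixels selected by ``restrict``); ``fixed`` uses ``fixed_value``.
    ``polarity`` chooses which side is foreground: ``above`` keeps strictly
    greater values, ``below`` the complement.
    """
    if polarity not in ("above", "below"):
        raise InvalidParameterError(f"unknown polarity {polarity!r}")
    values = index_map.values
    if strategy == "fixed":
        if fixed_value is None:
            raise InvalidParameterError("fixed strategy requires fixed_value")
        cut = float(fixed_value)
        fg = values >= cut if polarity == "above" else values < cut
        return Mask(fg, index_map.index_name.lower().replace("_", ""))
    if strategy != "otsu":
        raise InvalidParameterError(f"unknown threshold strategy {strategy!r}")
    sample = values if restrict is None else values[np.asarray(restrict, bool)]
    if sample.size == 0 or np.ptp(sample) == 0:
        raise DegenerateHistogramError(
            "index map is constant over the thresholding region; automatic "
            "Otsu thresholding is undefined — use strategy='fixed'")
    cut = float(threshold_otsu(sample.ravel(), nbins=256))
    fg = values > cut if polarity == "above" else values <= cut
    return Mask(fg, index_map.index_name.lower().replace("_", ""))


def tree_mask(image: RasterImage, strategy: str = "otsu",
              fixed_value: float | None = None,
              ipca_variant: str = "verbatim") -> Mask:
    """Canopy-vs-ground mask: high I_PCA is foreground."""
    idx = ipca_index(image, variant=ipca_variant)
    m = threshold_index(idx, strategy=strategy, fixed_value=fixed_value,
                        polarity="above")
    m.provenance = "ipca"
    return m


def fruit_mask(image: RasterImage, method: str = "hsv",
               hsv_range: HSVRange | None = None,
               tree: Mask | None = None,
               tree_strategy: str = "otsu",
               tree_fixed_value: float | None = None,
               ipca_variant: str = "verbatim") -> Mask:
    """Fruit pixels: the chosen candidate rule intersected with the tree mask.

    ``method`` is one of ``hsv`` (the color box, computed on the given —
    possibly equalized — image), ``ipca``, ``cive`` or ``i1`` (index computed
    on the given raw image, Otsu-thresholded over tree pixels only, with the
    polarity that puts orange fruit in the foreground).  The result is always
    a subset of the tree mask.
    """
    if tree is None:
        tree = tree_mask(image, strategy=tree_strategy,
                         fixed_value=tree_fixed_value, ipca_variant=ipca_variant)
    if method == "hsv":
        candidate = hsv_threshold(rgb_to_hsv_255(image), hsv_range)
    elif method in _INDEX_FUNCS:
        idx = _INDEX_FUNCS[method](image)
        candidate = threshold_index(idx, strategy="otsu",
                                    polarity=_FRUIT_POLARITY[method],
                                    restrict=tree.values)
    else:
        raise InvalidParameterError(f"unknown fruit detection method {method!r}")
    return candidate.intersection(tree)


def count_pixels(mask: Mask, roi: TreeROI) -> int:
    """Number of true mask pixels whose centers fall inside the ROI polygon.

    Pixel (x, y) has its center at coordinates (x, y); boundary pixels are
    included.  An ROI lying entirely outside the raster yields 0 with a
    warning rather than an error.
    """
    h, w = mask.shape
    poly = roi.shapely()
    minx, miny, maxx, maxy = poly.bounds
    if maxx < 0 or maxy < 0 or minx > w - 1 or miny > h - 1:
        warnings.warn(f"ROI {roi.label!r} lies entirely outside the image; "
                      "count is 0", stacklevel=2)
        return 0
    ys, xs = np.nonzero(mask.values)
    if xs.size == 0:
        return 0
    # restrict to the polygon bounding box before the exact test
    box = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
    xs, ys = xs[box], ys[box]
    if xs.size == 0:
        return 0
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, xs.astype(float), ys.astype(float))
    return int(np.count_nonzero(inside))


def roi_pixel_area(roi: TreeROI, shape: tuple[int, int]) -> int:
    """Number of raster pixel centers covered by the ROI (for bounds checks)."""
    full = Mask(np.ones(shape, dtype=bool), "hsv")
    return count_pixels(full, roi)
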