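"""Synthetic orchard scenes with known per-tree fruit counts.

The generator places non-overlapping circular crowns on a flat, non-vegetated
field and scatters orange fruit discs of known diameter inside each crown.
The renderer maps ground coordinates to pixels with exactly the camera
geometry module (so one fruit disc occupies the pixels-per-fruit area of the
altitude it is rendered at), optionally area-averages sub-pixel samples (a
crude model of sensor pixel integration — this, not added blur, is what makes
fruit edges blend into canopy at high altitude), and applies a global dimming
gain before 8-bit quantization so histogram equalization has something to
undo.

Surfaces are five-component color mixtures: base soil, brighter soil patches,
shaded canopy, sunlit canopy and fruit, each an RGB mean with per-channel
Gaussian noise.  The two "extra" components (bright soil, sunlit leaves) give
each channel histogram mass above the fruit's green value; without them,
per-channel equalization of a three-delta histogram sends both fruit R and G
to 255, the hue collapses to 60 deg and leaves the citrus hue band — an
artifact of over-simplified scenes, not of the method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .camera import CameraModel, ground_sample_distance_cm
from .errors import InvalidParameterError, PackingError
from .preprocess import RasterImage
from .segment import TreeROI

__all__ = [
    "SceneSpec", "Tree", "World", "TreeTruth", "GroundTruth",
    "generate_scene", "render", "he_benefit_fixture",
    "fruit_truth_mask", "truth_rois",
]

RGB = tuple[float, float, float]


@dataclass(frozen=True)
class SceneSpec:
    """All knobs of a synthetic scene; the seed fully determines it.

    Defaults emulate the surveyed plots: three trees per frame in a field
    matching the 30 m footprint, ~118 fruits per tree (the mean of the
    reported actual yields 124/88/141), 46.7 mm fruit, and a visible
    fraction of 0.75 standing in for canopy occlusion.
    """

    n_trees: int = 3
    field_width_m: float = 14.8
    field_height_m: float = 11.1
    canopy_radius_mean_m: float = 1.6
    canopy_radius_sd_m: float = 0.15
    fruits_per_tree_mean: float = 118.0
    #: gamma-Poisson shape; larger is closer to Poisson, None is Poisson.
    fruits_per_tree_dispersion: float | None = 20.0
    fruit_diameter_mm: float = 46.7
    visible_fraction: float = 0.75
    ground_color: RGB = (150.0, 140.0, 125.0)
    ground_color_sd: RGB = (10.0, 10.0, 10.0)
    ground_bright_color: RGB = (210.0, 204.0, 192.0)
    ground_bright_sd: RGB = (10.0, 10.0, 10.0)
    ground_bright_fraction: float = 0.10
    canopy_color: RGB = (40.0, 95.0, 30.0)
    canopy_color_sd: RGB = (8.0, 8.0, 8.0)
    canopy_sunlit_color: RGB = (85.0, 200.0, 60.0)
    canopy_sunlit_sd: RGB = (12.0, 12.0, 12.0)
    canopy_sunlit_fraction: float = 0.30
    fruit_color: RGB = (245.0, 185.0, 95.0)
    fruit_color_sd: RGB = (6.0, 6.0, 6.0)
    global_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InvalidParameterError("n_trees must be >= 1")
        for name in ("visible_fraction", "ground_bright_fraction",
                     "canopy_sunlit_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if not 0.0 < self.global_gain <= 1.0:
            raise InvalidParameterError("global_gain must be in (0, 1]")
        if self.fruit_diameter_mm <= 0:
            raise InvalidParameterError("fruit_diameter_mm must be > 0")


@dataclass(frozen=True)
class Tree:
    label: str
    center_m: tuple[float, float]  # (x, y) ground coordinates
    radius_m: float
    fruit_xy_m: np.ndarray  # (n, 2) positions of all fruits
    visible: np.ndarray  # (n,) bool, rendered or occluded


@dataclass(frozen=True)
class World:
    spec: SceneSpec
    trees: tuple[Tree, ...]


@dataclass(frozen=True)
class TreeTruth:
    label: str
    polygon_px: np.ndarray  # crown outline, (x, y) pixel coordinates
    true_fruit_total: int
    visible_fruit: int
    fruit_centers_px: np.ndarray  # (visible_fruit, 2) (x, y)


@dataclass(frozen=True)
class GroundTruth:
    trees: tuple[TreeTruth, ...]
    image_shape: tuple[int, int]  # (H, W)
    fruit_radius_x_px: float
    fruit_radius_y_px: float
    altitude_m: float


def generate_scene(spec: SceneSpec) -> World:
    """Place crowns (rejection sampling, no overlap) and fruits (uniform in
    each crown disk) on the field.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    trees: list[Tree] = []
    placed: list[tuple[float, float, float]] = []
    max_tries = 1000 * spec.n_trees
    tries = 0
    while len(placed) < spec.n_trees:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {spec.n_trees} non-overlapping crowns in a "
                f"{spec.field_width_m} x {spec.field_height_m} m field after "
                f"{max_tries} tries")
        tries += 1
        radius = float(np.clip(
            rng.normal(spec.canopy_radius_mean_m, spec.canopy_radius_sd_m),
            0.3, None))
        if 2 * radius >= min(spec.field_width_m, spec.field_height_m):
            continue
        cx = rng.uniform(radius, spec.field_width_m - radius)
        cy = rng.uniform(radius, spec.field_height_m - radius)
        if any((cx - ox) ** 2 + (cy - oy) ** 2 < (radius + orad) ** 2
               for ox, oy, orad in placed):
            continue
        placed.append((cx, cy, radius))
    for i, (cx, cy, radius) in enumerate(placed, start=1):
        if spec.fruits_per_tree_dispersion is None:
            n_fruit = int(rng.poisson(spec.fruits_per_tree_mean))
        else:
            k = spec.fruits_per_tree_dispersion
            lam = rng.gamma(k, spec.fruits_per_tree_mean / k)
            n_fruit = int(rng.poisson(lam))
        # uniform in the crown disk, kept off the very rim so centers stay
        # inside the polygonal crown outline
        u = rng.random(n_fruit)
        theta = rng.uniform(0.0, 2.0 * math.pi, n_fruit)
        rr = 0.97 * radius * np.sqrt(u)
        xy = np.column_stack([cx + rr * np.cos(theta),
                              cy + rr * np.sin(theta)])
        visible = rng.random(n_fruit) < spec.visible_fraction
        trees.append(Tree(f"tree_{i}", (cx, cy), radius, xy, visible))
    return World(spec, tuple(trees))


def _class_map(world: World, gx_cm: float, gy_cm: float,
               shape_px: tuple[int, int], s: int) -> np.ndarray:
    """0 = ground, 1 = canopy, 2 = fruit, on the supersampled grid."""
    h, w = shape_px
    cls = np.zeros((h * s, w * s), dtype=np.uint8)
    spec = world.spec
    fruit_r_cm = spec.fruit_diameter_mm / 20.0
    for tree in world.trees:
        cx, cy = tree.center_m
        rr, cc = _draw_ellipse(
            cy * 100.0 * s / gy_cm - 0.5, cx * 100.0 * s / gx_cm - 0.5,
            tree.radius_m * 100.0 * s / gy_cm, tree.radius_m * 100.0 * s / gx_cm,
            shape=cls.shape)
        cls[rr, cc] = 1
    for tree in world.trees:
        for (fx, fy) in tree.fruit_xy_m[tree.visible]:
            rr, cc = _draw_ellipse(
                fy * 100.0 * s / gy_cm - 0.5, fx * 100.0 * s / gx_cm - 0.5,
                fruit_r_cm * s / gy_cm, fruit_r_cm * s / gx_cm,
                shape=cls.shape)
            cls[rr, cc] = 2
    return cls


def _coverage(cls: np.ndarray, value: int, h: int, w: int, s: int) -> np.ndarray:
    one = (cls == value).astype(np.float32)
    return one.reshape(h, s, w, s).mean(axis=(1, 3))


def render(world: World, camera: CameraModel | None = None,
           altitude_m: float = 30.0, supersample: int = 1,
           ) -> tuple[RasterImage, GroundTruth]:
    """Rasterize a world at the pixel scale of one altitude.

    ``supersample`` area-averages an s x s sub-pixel grid per pixel
    (``supersample=1`` is crisp nearest rasterization).  Colors are the
    coverage-weighted component means plus Gaussian noise, clamped to
    [0, 255], multiplied by ``global_gain`` and quantized to 8 bits.  The
    ground truth is expressed in the rendered pixel frame.
    """
    camera = camera if camera is not None else CameraModel()
    if altitude_m <= 0:
        raise InvalidParameterError("altitude must be > 0")
    if supersample < 1:
        raise InvalidParameterError("supersample must be >= 1")
    spec = world.spec
    gx_cm, gy_cm = ground_sample_distance_cm(camera, altitude_m)
    w_px = min(int(math.ceil(spec.field_width_m * 100.0 / gx_cm)),
               camera.image_width_px)
    h_px = min(int(math.ceil(spec.field_height_m * 100.0 / gy_cm)),
               camera.image_height_px)
    s = int(supersample)
    cls = _class_map(world, gx_cm, gy_cm, (h_px, w_px), s)

    rng = np.random.default_rng([spec.seed, int(round(altitude_m * 1000)), s])
    means = np.array([spec.ground_color, spec.ground_bright_color,
                      spec.canopy_color, spec.canopy_sunlit_color,
                      spec.fruit_color], dtype=np.float32)
    sds = np.array([spec.ground_color_sd, spec.ground_bright_sd,
                    spec.canopy_color_sd, spec.canopy_sunlit_sd,
                    spec.fruit_color_sd], dtype=np.float32)
    bright = rng.random((h_px, w_px)) < spec.ground_bright_fraction
    sunlit = rng.random((h_px, w_px)) < spec.canopy_sunlit_fraction
    if s == 1:
        # one-hot coverage: a single LUT gather per pixel
        comp = np.where(bright, 1, 0).astype(np.uint8)
        canopy = cls == 1
        comp[canopy] = 2
        comp[canopy & sunlit] = 3
        comp[cls == 2] = 4
        del cls, canopy
        img = means[comp]
        sd_eff = sds[comp]
    else:
        w_canopy = _coverage(cls, 1, h_px, w_px, s)
        w_fruit = _coverage(cls, 2, h_px, w_px, s)
        del cls
        w_ground = 1.0 - w_canopy - w_fruit
        weights = (
            (w_ground * ~bright, 0), (w_ground * bright, 1),
            (w_canopy * ~sunlit, 2), (w_canopy * sunlit, 3),
            (w_fruit, 4),
        )
        img = np.zeros((h_px, w_px, 3), dtype=np.float32)
        sd_eff = np.zeros((h_px, w_px, 3), dtype=np.float32)
        for wgt, k in weights:
            img += wgt[..., None] * means[k]
            sd_eff += wgt[..., None] * sds[k]
        sd_eff /= s  # sub-pixel noise averages down
    img += rng.standard_normal(img.shape, dtype=np.float32) * sd_eff
    del sd_eff
    np.clip(img, 0.0, 255.0, out=img)
    img *= spec.global_gain
    pixels = np.floor(img + 0.5).astype(np.uint8)

    # ground truth in pixel coordinates
    fruit_r_cm = spec.fruit_diameter_mm / 20.0
    frx, fry = fruit_r_cm / gx_cm, fruit_r_cm / gy_cm
    ang = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
    truths = []
    for tree in world.trees:
        cx, cy = tree.center_m
        poly = np.column_stack([
            (cx + tree.radius_m * np.cos(ang)) * 100.0 / gx_cm - 0.5,
            (cy + tree.radius_m * np.sin(ang)) * 100.0 / gy_cm - 0.5,
        ])
        centers = np.column_stack([
            tree.fruit_xy_m[tree.visible, 0] * 100.0 / gx_cm - 0.5,
            tree.fruit_xy_m[tree.visible, 1] * 100.0 / gy_cm - 0.5,
        ])
        truths.append(TreeTruth(
            label=tree.label,
            polygon_px=poly,
            true_fruit_total=int(tree.visible.size),
            visible_fruit=int(tree.visible.sum()),
            fruit_centers_px=centers,
        ))
    truth = GroundTruth(tuple(truths), (h_px, w_px), frx, fry, altitude_m)
    return RasterImage(pixels, "RGB"), truth


def fruit_truth_mask(truth: GroundTruth) -> np.ndarray:
    """Boolean raster of the geometrically rendered (visible) fruit pixels."""
    mask = np.zeros(truth.image_shape, dtype=bool)
    for tree in truth.trees:
        for (fx, fy) in tree.fruit_centers_px:
            rr, cc = _draw_ellipse(fy, fx, truth.fruit_radius_y_px,
                                   truth.fruit_radius_x_px, shape=mask.shape)
            mask[rr, cc] = True
    return mask


def truth_rois(truth: GroundTruth) -> list[TreeROI]:
    """Crown outlines as ROI polygons for the segmentation module."""
    return [TreeROI(t.label, t.polygon_px) for t in truth.trees]


def he_benefit_fixture(spec: SceneSpec | None = None, altitude_m: float = 30.0,
                       camera: CameraModel | None = None, supersample: int = 1,
                       **overrides) -> tuple[RasterImage, GroundTruth]:
    """A dimmed scene on which equalization measurably raises fruit counts.

    The default gain (0.8) pushes fruit brightness below the V >= 221 cut in
    the raw rendering while equalization — which is invariant to a global
    gain up to quantization — restores it.  Seed-deterministic.
    """
    base = spec if spec is not None else SceneSpec(
        n_trees=2, field_width_m=5.5, field_height_m=4.5,
        canopy_radius_mean_m=1.1, fruits_per_tree_mean=50.0,
        global_gain=0.8, seed=7)
    if overrides:
        base = replace(base, **overrides)
    world = generate_scene(base)
    return render(world, camera, altitude_m, supersample=supersample)
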