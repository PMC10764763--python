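"""Flight-altitude camera geometry.

A nadir image taken from altitude *a* with a pinhole camera of focal length
*f* covers a ground rectangle of ``a * sensor_dim / f`` per axis (similar
triangles).  From that footprint follow the areal pixel density (px/cm²) and
the pixel area of an average citrus fruit — the divisor that converts
fruit-pixel counts into fruit numbers.

All scale conversions in the package go through :class:`CameraModel`; nothing
else hard-codes a ground-sample distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import InvalidParameterError

__all__ = [
    "CameraModel",
    "FruitModel",
    "AltitudeProfile",
    "DEFAULT_ALTITUDES_M",
    "PRINTED_FRUIT_AREA_CM2",
    "round_half_up",
    "ground_footprint",
    "pixel_density",
    "ground_sample_distance_cm",
    "pixels_per_fruit",
    "altitude_profile",
    "altitude_table",
    "min_altitude_for_resolution",
]

#: The five survey altitudes flown in the study this package reproduces.
DEFAULT_ALTITUDES_M = (30.0, 50.0, 70.0, 90.0, 110.0)

#: The truncated per-fruit cross-section sometimes quoted in agency reports
#: (cm²/fruit).  Kept for documentation; computations use the exact circle
#: area, which is what reproduces the published pixels-per-fruit column.
PRINTED_FRUIT_AREA_CM2 = 17.12


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero toward +inf (0.5 -> 1).

    Python's ``round`` and numpy's ``np.round`` are banker's rounding; the
    published tables were rounded half-up, and the 18 px / 110 m cell (raw
    estimate 0.52) only reproduces under half-up.
    """
    scale = 10.0 ** decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class CameraModel:
    """Sensor dimensions, focal length and pixel grid of the survey camera.

    Defaults describe the RGB camera used in the study: 13 mm x 17.3 mm
    sensor, 35 mm focal length, 5460 x 8192 px images.  The sensor long axis
    maps to the image long axis.
    """

    sensor_width_mm: float = 17.3
    sensor_height_mm: float = 13.0
    focal_length_mm: float = 35.0
    image_width_px: int = 8192
    image_height_px: int = 5460

    def __post_init__(self) -> None:
        for name in ("sensor_width_mm", "sensor_height_mm", "focal_length_mm",
                     "image_width_px", "image_height_px"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        sensor_aspect = self.sensor_width_mm / self.sensor_height_mm
        grid_aspect = self.image_width_px / self.image_height_px
        if abs(sensor_aspect / grid_aspect - 1.0) > 0.05:
            warnings.warn(
                "sensor aspect ratio differs from pixel-grid aspect ratio by "
                f"more than 5% ({sensor_aspect:.3f} vs {grid_aspect:.3f}); "
                "ground pixels will be strongly anisotropic",
                stacklevel=2,
            )


@dataclass(frozen=True)
class FruitModel:
    """Average fruit geometry used for the pixel-to-count calibration.

    The default diameter is the 2021 provincial average for Citrus unshiu,
    46.7 mm.  The cross-section is the exact circle area pi*(d/2)^2
    (~17.1287 cm²), not the truncated 17.12 cm² sometimes printed.
    """

    diameter_mm: float = 46.7
    cross_section_area_cm2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise InvalidParameterError("fruit diameter must be > 0")
        object.__setattr__(
            self, "cross_section_area_cm2",
            math.pi * (self.diameter_mm / 20.0) ** 2,
        )


@dataclass(frozen=True)
class AltitudeProfile:
    """Derived ground scale at one flight altitude."""

    altitude_m: float
    footprint_width_m: float
    footprint_height_m: float
    footprint_area_ha: float
    pixels_per_cm2: float
    pixels_per_fruit: float

    @property
    def pixels_per_fruit_int(self) -> int:
        """Half-up rounded integer view, for reporting."""
        return int(round_half_up(self.pixels_per_fruit))

    @property
    def pixels_per_cm2_int(self) -> int:
        return int(round_half_up(self.pixels_per_cm2))

    @property
    def footprint_area_ha_2dp(self) -> float:
        return round_half_up(self.footprint_area_ha, 2)


def _check_altitude(altitude_m: float) -> None:
    if not altitude_m > 0:
        raise InvalidParameterError(f"altitude must be > 0 m, got {altitude_m}")


def ground_footprint(camera: CameraModel, altitude_m: float) -> tuple[float, float, float]:
    """Ground rectangle covered by one image: (width m, height m, area ha).

    Each dimension is ``altitude * sensor_dim / focal_length``; the area is
    returned in hectares, unrounded.
    """
    _check_altitude(altitude_m)
    width_m = altitude_m * camera.sensor_width_mm / camera.focal_length_mm
    height_m = altitude_m * camera.sensor_height_mm / camera.focal_length_mm
    return width_m, height_m, width_m * height_m / 1e4


def pixel_density(camera: CameraModel, altitude_m: float) -> float:
    """Areal pixel density on the ground, in pixels per cm², unrounded."""
    width_m, height_m, _ = ground_footprint(camera, altitude_m)
    area_cm2 = (width_m * 100.0) * (height_m * 100.0)
    return camera.image_width_px * camera.image_height_px / area_cm2


def ground_sample_distance_cm(camera: CameraModel, altitude_m: float) -> tuple[float, float]:
    """Ground length of one pixel per image axis (x, y), in cm."""
    width_m, height_m, _ = ground_footprint(camera, altitude_m)
    return (width_m * 100.0 / camera.image_width_px,
            height_m * 100.0 / camera.image_height_px)


def pixels_per_fruit(camera: CameraModel, altitude_m: float,
                     fruit: FruitModel | None = None) -> float:
    """Pixel area of one average fruit at this altitude, unrounded.

    This is the divisor of the yield equation: pixel density times the exact
    circular cross-section of the average fruit.
    """
    fruit = fruit if fruit is not None else FruitModel()
    return pixel_density(camera, altitude_m) * fruit.cross_section_area_cm2


def altitude_profile(camera: CameraModel, altitude_m: float,
                     fruit: FruitModel | None = None) -> AltitudeProfile:
    fruit = fruit if fruit is not None else FruitModel()
    width_m, height_m, area_ha = ground_footprint(camera, altitude_m)
    density = pixel_density(camera, altitude_m)
    return AltitudeProfile(
        altitude_m=altitude_m,
        footprint_width_m=width_m,
        footprint_height_m=height_m,
        footprint_area_ha=area_ha,
        pixels_per_cm2=density,
        pixels_per_fruit=density * fruit.cross_section_area_cm2,
    )


def altitude_table(camera: CameraModel, fruit: FruitModel | None = None,
                   altitudes_m: tuple[float, ...] | list[float] = DEFAULT_ALTITUDES_M,
                   ) -> list[AltitudeProfile]:
    """One :class:`AltitudeProfile` per altitude, in the given order."""
    if len(altitudes_m) == 0:
        raise InvalidParameterError("altitude list must be non-empty")
    return [altitude_profile(camera, a, fruit) for a in altitudes_m]


def min_altitude_for_resolution(camera: CameraModel,
                                required_pixels_per_cm: float) -> float:
    """Largest altitude whose coarser-axis linear density meets a requirement.

    Linear density along an axis is ``image_px / ground_cm`` and scales as
    1/altitude, so the inversion is closed-form.  The coarser (fewer px/cm)
    axis governs: a feature must be resolved along both axes.
    """
    if not required_pixels_per_cm > 0:
        raise InvalidParameterError("required resolution must be > 0 px/cm")
    # px/cm at altitude a is k/a per axis with k = image_px * f / (100 * sensor_mm)
    k_w = camera.image_width_px * camera.focal_length_mm / (100.0 * camera.sensor_width_mm)
    k_h = camera.image_height_px * camera.focal_length_mm / (100.0 * camera.sensor_height_mm)
    return min(k_w, k_h) / required_pixels_per_cm


def linear_pixel_density(camera: CameraModel, altitude_m: float) -> float:
    """Coarser-axis linear pixel density (px per ground cm) at an altitude."""
    gsd_x, gsd_y = ground_sample_distance_cm(camera, altitude_m)
    return 1.0 / max(gsd_x, gsd_y)
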