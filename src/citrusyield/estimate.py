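"""Pixel-count to fruit-number conversion.

The yield equation is a plain ratio: estimated fruits = fruit pixels /
pixels-per-fruit at that altitude.  The divisor is the *unrounded*
pixels-per-fruit from the camera geometry (463.671 at 30 m, not 464) — the
load-bearing numerical choice of this package: the published per-tree
estimates and group means only reproduce with the exact divisor.  Reported
integers are rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass

from .camera import (AltitudeProfile, CameraModel, FruitModel,
                     altitude_profile, round_half_up)
from .errors import DuplicateKeyError, InvalidParameterError

__all__ = ["TreeEstimate", "estimate_fruit_count", "estimate_table"]


@dataclass(frozen=True)
class TreeEstimate:
    """Per-tree result row: pixel count, divisor, raw and rounded estimate."""

    tree_label: str
    altitude_m: float
    fruit_pixels: int
    pixels_per_fruit: float
    estimate_raw: float
    estimate: int


def estimate_fruit_count(fruit_pixels: int, profile: AltitudeProfile,
                         tree_label: str = "") -> TreeEstimate:
    """Convert one fruit-pixel count into a fruit-number estimate."""
    if fruit_pixels < 0:
        raise InvalidParameterError("fruit_pixels must be >= 0")
    if not profile.pixels_per_fruit > 0:
        raise InvalidParameterError(
            "profile has non-positive pixels_per_fruit; cannot divide")
    raw = fruit_pixels / profile.pixels_per_fruit
    return TreeEstimate(
        tree_label=tree_label,
        altitude_m=profile.altitude_m,
        fruit_pixels=int(fruit_pixels),
        pixels_per_fruit=profile.pixels_per_fruit,
        estimate_raw=raw,
        estimate=int(round_half_up(raw)),
    )


def estimate_table(counts: list[tuple[str, float, int]],
                   camera: CameraModel | None = None,
                   fruit: FruitModel | None = None) -> list[TreeEstimate]:
    """One :class:`TreeEstimate` per (label, altitude, fruit_pixels) row.

    Rows are returned in deterministic order (altitude ascending, then
    label); duplicate (label, altitude) keys are rejected.
    """
    if not counts:
        raise InvalidParameterError("counts must be non-empty")
    camera = camera if camera is not None else CameraModel()
    fruit = fruit if fruit is not None else FruitModel()
    seen: set[tuple[str, float]] = set()
    profiles: dict[float, AltitudeProfile] = {}
    rows = []
    for label, altitude_m, fruit_pixels in counts:
        key = (label, float(altitude_m))
        if key in seen:
            raise DuplicateKeyError(
                f"duplicate (label, altitude) pair {key}")
        seen.add(key)
        prof = profiles.get(float(altitude_m))
        if prof is None:
            prof = altitude_profile(camera, float(altitude_m), fruit)
            profiles[float(altitude_m)] = prof
        rows.append(estimate_fruit_count(int(fruit_pixels), prof, label))
    rows.sort(key=lambda r: (r.altitude_m, r.tree_label))
    return rows
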