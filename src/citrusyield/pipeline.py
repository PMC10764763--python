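"""End-to-end orchestration and file I/O shared by the CLI.

Per image: (optional) histogram equalization -> fruit mask -> per-ROI pixel
counts -> fruit-number estimates; across a raw/equalized treatment pair:
group comparison.  Every stage writes a CSV with a stable header, and each
run leaves a JSON manifest (config echo, package version, inputs) so results
can be reproduced byte-for-byte apart from the timestamp field.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .camera import altitude_profile, altitude_table
from .config import PipelineConfig
from .errors import CitrusYieldError, FormatError
from .estimate import TreeEstimate, estimate_fruit_count
from .preprocess import RasterImage, equalize_histogram
from .segment import Mask, TreeROI, count_pixels, fruit_mask
from .stats import compare_treatments

log = logging.getLogger("citrusyield")

ALTITUDE_CSV_HEADER = ["altitude_m", "footprint_w_m", "footprint_h_m",
                       "area_ha", "px_per_cm2", "px_per_fruit"]
COUNTS_CSV_HEADER = ["tree_label", "fruit_pixels"]
ESTIMATE_CSV_HEADER = ["tree_label", "altitude_m", "fruit_pixels",
                       "px_per_fruit", "estimate_raw", "estimate"]
COMPARE_CSV_HEADER = ["altitude_m", "metric", "mean_a", "disp_a", "mean_b",
                      "disp_b", "test", "p_value", "label"]


def read_image(path: str | Path) -> RasterImage:
    """Load an 8-bit RGB raster (PNG/TIFF/JPEG); 16-bit inputs are rejected."""
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise FormatError(
                f"{path}: 16-bit/float images are not supported; the "
                "pipeline is 8-bit throughout — convert to 8-bit first")
        arr = np.asarray(im.convert("RGB"))
    return RasterImage(arr, "RGB")


def write_image(image: RasterImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode=image.color_space).save(path)


def write_mask(mask: Mask, path: str | Path) -> None:
    """Persist a boolean mask as a 1-bit PNG."""
    Image.fromarray(mask.values).convert("1").save(path)


def read_rois(path: str | Path) -> list[TreeROI]:
    """ROI JSON: ``[{"label": str, "polygon": [[x, y], ...]}, ...]`` in
    0-based pixel coordinates, origin top-left, x rightward, y downward."""
    with open(path) as fh:
        data = json.load(fh)
    return [TreeROI(item["label"], np.asarray(item["polygon"], float))
            for item in data]


def write_rois(rois: Iterable[TreeROI], path: str | Path) -> None:
    data = [{"label": r.label, "polygon": np.asarray(r.polygon).tolist()}
            for r in rois]
    Path(path).write_text(json.dumps(data, indent=1))


def altitude_table_frame(config: PipelineConfig) -> pd.DataFrame:
    """The flight-planning table (one row per altitude) as a DataFrame."""
    rows = []
    for prof in altitude_table(config.camera, config.fruit, config.altitudes_m):
        rows.append([prof.altitude_m, prof.footprint_width_m,
                     prof.footprint_height_m, prof.footprint_area_ha,
                     prof.pixels_per_cm2, prof.pixels_per_fruit])
    return pd.DataFrame(rows, columns=ALTITUDE_CSV_HEADER)


def segment_image(image: RasterImage, rois: list[TreeROI],
                  config: PipelineConfig) -> tuple[Mask, pd.DataFrame]:
    """Preprocess + segment + count for one image."""
    seg = config.segmentation
    work = equalize_histogram(image) if seg.equalize else image
    mask = fruit_mask(work, method=seg.method, hsv_range=seg.hsv_range,
                      tree_strategy=seg.tree_strategy,
                      tree_fixed_value=seg.tree_fixed_value,
                      ipca_variant=seg.ipca_variant)
    counts = [[roi.label, count_pixels(mask, roi)] for roi in rois]
    return mask, pd.DataFrame(counts, columns=COUNTS_CSV_HEADER)


def estimates_frame(estimates: Iterable[TreeEstimate]) -> pd.DataFrame:
    rows = [[e.tree_label, e.altitude_m, e.fruit_pixels, e.pixels_per_fruit,
             e.estimate_raw, e.estimate] for e in estimates]
    return pd.DataFrame(rows, columns=ESTIMATE_CSV_HEADER)


def estimates_from_frame(frame: pd.DataFrame) -> list[TreeEstimate]:
    return [TreeEstimate(str(r.tree_label), float(r.altitude_m),
                         int(r.fruit_pixels), float(r.px_per_fruit),
                         float(r.estimate_raw), int(r.estimate))
            for r in frame.itertuples()]


def comparison_frame(results) -> pd.DataFrame:
    rows = [[c.altitude_m, c.metric, c.summary_a.mean,
             c.summary_a.paper_style_dispersion, c.summary_b.mean,
             c.summary_b.paper_style_dispersion, c.test, c.p_value,
             c.significance_label] for c in results]
    return pd.DataFrame(rows, columns=COMPARE_CSV_HEADER)


def run_pipeline(config: PipelineConfig,
                 images: list[tuple[str, float, str]],
                 output_dir: str | Path | None = None) -> dict:
    """Process (image path, altitude, roi path) triples end to end.

    Writes per-image count and estimate CSVs plus a manifest; failures on
    individual images are logged and skipped, and reported in the returned
    summary (``n_failed`` > 0 signals a partial run).
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_estimates: list[TreeEstimate] = []
    failed: list[str] = []
    for img_path, altitude_m, roi_path in images:
        try:
            image = read_image(img_path)
            rois = read_rois(roi_path)
            mask, counts = segment_image(image, rois, config)
            stem = Path(img_path).stem
            write_mask(mask, out / f"{stem}_mask.png")
            counts.to_csv(out / f"{stem}_counts.csv", index=False)
            prof = altitude_profile(config.camera, altitude_m, config.fruit)
            ests = [estimate_fruit_count(int(c), prof, str(lbl))
                    for lbl, c in counts.itertuples(index=False)]
            estimates_frame(ests).to_csv(out / f"{stem}_estimates.csv",
                                         index=False)
            all_estimates.extend(ests)
            log.info("processed %s at %.0f m: %d ROIs", img_path, altitude_m,
                     len(rois))
        except (OSError, CitrusYieldError, KeyError) as exc:
            log.error("skipping %s: %s", img_path, exc)
            failed.append(str(img_path))
    estimates_frame(all_estimates).to_csv(out / "estimates.csv", index=False)
    manifest = {
        "package": "citrusyield",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "images": [[str(p), a, str(r)] for p, a, r in images],
        "n_failed": len(failed),
        "failed": failed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


def compare_tables(frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                   config: PipelineConfig) -> pd.DataFrame:
    results = compare_treatments(
        estimates_from_frame(frame_a), estimates_from_frame(frame_b),
        metric=config.stats.metric, alpha=config.stats.alpha,
        t_variant=config.stats.t_variant, test=config.stats.test)
    return comparison_frame(results)
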