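"""Reading and writing slide rasters and pipeline tables.

A slide is stored as a three-page TIFF (instance map, class map, layer
mask, in that order) with the microns-per-pixel recorded in the page
description; tables are plain CSV with the column names used throughout
the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import SlideRaster

__all__ = ["write_slide", "read_slide", "write_cohort"]


def write_slide(slide: SlideRaster, path: str | Path) -> None:
    """Write a slide's three label maps as a multi-page TIFF."""
    meta = json.dumps({"mpp": slide.mpp, "pages": ["instance", "class", "layer"]})
    with tifffile.TiffWriter(str(path)) as tif:
        tif.write(slide.instance_map.astype(np.int32), description=meta)
        tif.write(slide.class_map.astype(np.uint8))
        tif.write(slide.layer_mask.astype(np.uint8))


def read_slide(path: str | Path) -> SlideRaster:
    """Read a slide written by :func:`write_slide`."""
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description
    meta = json.loads(desc)
    return SlideRaster(
        instance_map=pages[0].astype(np.int32),
        class_map=pages[1].astype(np.uint8),
        layer_mask=pages[2].astype(np.uint8),
        mpp=float(meta["mpp"]),
    )


def write_cohort(cohort, out_dir: str | Path) -> None:
    """Write a generated cohort: per-slide TIFFs plus CSV tables."""
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    for i, (slide, truth) in enumerate(zip(cohort.slides, cohort.truths)):
        write_slide(slide, out / "slides" / f"slide_{i:04d}.tiff")
        truth.to_csv(out / "slides" / f"slide_{i:04d}_nuclei.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.outcomes.to_csv(out / "outcomes.csv", index=False)
    cohort.heatmaps.to_csv(out / "heatmaps.csv", index=False)
    cohort.slide_features.to_csv(out / "slide_truth_features.csv", index=False)
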