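"""Patch-grid extraction over the epithelium mask.

Tiles are enumerated row-major from origin (0, 0) with a stride of
``patch_size * (1 - overlap)``; a tile is retained iff its
epithelium-pixel fraction (keratin + epithelial + basal) meets the
configured threshold.  Windows that would overrun the raster are dropped,
never padded.  Coordinates are 0-based (row, col) with half-open extents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .labels import EPITHELIUM_LAYERS
from .synthetic import SlideRaster

logger = logging.getLogger(__name__)

__all__ = ["PatchingConfig", "PatchWindow", "extract_patch_grid", "crop_patch", "nuclei_in_window"]


@dataclass(frozen=True)
class PatchingConfig:
    """Tiling parameters: 512x512 tiles, 50% overlap, 0.50 um/px."""

    patch_size: tuple[int, int] = (512, 512)
    overlap: float = 0.5
    mpp_target: float = 0.50
    min_epithelium_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if any(s <= 0 for s in self.patch_size):
            raise ValueError("patch_size must be positive")
        if not (0 <= self.min_epithelium_fraction <= 1):
            raise ValueError("min_epithelium_fraction must be in [0, 1]")

    @property
    def stride(self) -> tuple[int, int]:
        m, n = self.patch_size
        return (max(int(round(m * (1 - self.overlap))), 1), max(int(round(n * (1 - self.overlap))), 1))


@dataclass(frozen=True)
class PatchWindow:
    """Half-open window [row0, row0+rows) x [col0, col0+cols)."""

    slide_id: int
    index: int
    row0: int
    col0: int
    rows: int
    cols: int
    epithelium_fraction: float = float("nan")

    def contains_point(self, row: float, col: float) -> bool:
        return (
            self.row0 <= row < self.row0 + self.rows
            and self.col0 <= col < self.col0 + self.cols
        )


def extract_patch_grid(
    layer_mask: np.ndarray,
    config: PatchingConfig | None = None,
    slide_id: int = 0,
) -> list[PatchWindow]:
    """Enumerate retained tiles over a layer mask.

    Returns an empty list (with a logged warning) when the mask is smaller
    than one tile.  Retention uses an integral image of the epithelium
    indicator, so cost is O(H*W + #windows).
    """
    config = config or PatchingConfig()
    h, w = layer_mask.shape
    m, n = config.patch_size
    if h < m or w < n:
        logger.warning("layer mask %s smaller than patch size %s; no windows", (h, w), (m, n))
        return []
    epi = np.isin(layer_mask, np.array(EPITHELIUM_LAYERS, dtype=layer_mask.dtype))
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(epi, axis=0), axis=1, out=integral[1:, 1:])

    sr, sc = config.stride
    windows: list[PatchWindow] = []
    idx = 0
    for r0 in range(0, h - m + 1, sr):
        for c0 in range(0, w - n + 1, sc):
            s = (
                integral[r0 + m, c0 + n]
                - integral[r0, c0 + n]
                - integral[r0 + m, c0]
                + integral[r0, c0]
            )
            frac = s / (m * n)
            if frac >= config.min_epithelium_fraction:
                windows.append(PatchWindow(slide_id, idx, r0, c0, m, n, float(frac)))
                idx += 1
    return windows


def crop_patch(slide: SlideRaster, window: PatchWindow) -> SlideRaster:
    """Crop a window out of a slide; instance ids are preserved."""
    h, w = slide.instance_map.shape
    if (
        window.row0 < 0
        or window.col0 < 0
        or window.row0 + window.rows > h
        or window.col0 + window.cols > w
    ):
        raise ValueError(f"window {window} lies outside the {h}x{w} raster")
    rs = slice(window.row0, window.row0 + window.rows)
    cs = slice(window.col0, window.col0 + window.cols)
    return SlideRaster(
        slide.instance_map[rs, cs],
        slide.class_map[rs, cs],
        slide.layer_mask[rs, cs],
        slide.mpp,
    )


def nuclei_in_window(nuclei, window: PatchWindow, row_col=("centre_row", "centre_col")):
    """Select nuclei whose centroid lies inside the half-open window.

    Centroid-in-window membership prevents double counting across
    overlapping tiles.
    """
    r, c = row_col
    inside = (
        (nuclei[r] >= window.row0)
        & (nuclei[r] < window.row0 + window.rows)
        & (nuclei[c] >= window.col0)
        & (nuclei[c] < window.col0 + window.cols)
    )
    return nuclei[inside]
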