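"""Per-nucleus morphometry and per-patch, per-compartment aggregation.

Shape descriptors follow standard regionprops conventions: extent is
area over bounding-box area, equivalent diameter is ``sqrt(4*area/pi)``,
eccentricity and axis lengths come from the ellipse with matching second
central moments, convex area is the convex-hull pixel count, and the
centroid is the area centroid.  All lengths are reported in microns (via
the slide's microns-per-pixel) so features are resolution independent.

Proximity features — nearest-neighbour distance and the number of other
nuclei within 100 um — are computed within one patch and compartment,
matching the layer-wise reporting of everything else.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .labels import COMPARTMENTS, LAYER_BY_NAME, LAYER_NAMES, NucleusClass, TissueLayer
from .patching import PatchWindow, nuclei_in_window
from .synthetic import SlideRaster

__all__ = [
    "SHAPE_FEATURES",
    "MORPHOMETRIC_FEATURES",
    "nucleus_features",
    "assign_compartment",
    "nucleus_feature_table",
    "nearest_neighbour_distances",
    "local_density_counts",
    "aggregate_patch",
    "compute_patch_features",
]

#: shape descriptors produced per nucleus
SHAPE_FEATURES = (
    "area_um2",
    "extent",
    "equiv_diameter_um",
    "eccentricity",
    "convex_area_um2",
    "major_axis_um",
    "minor_axis_um",
    "bbox_area_um2",
)

#: everything aggregated per patch (shape + proximity)
MORPHOMETRIC_FEATURES = SHAPE_FEATURES + ("nnd_um", "count_100um")

_AGGS = ("min", "max", "mean", "median", "std")


def _shape_row(region, mpp: float) -> dict:
    area_px = region.area
    mjl = region.axis_major_length * mpp
    mnl = region.axis_minor_length * mpp
    ecc = region.eccentricity
    if mjl == 0.0:  # single pixel: degenerate second moments
        mjl = mnl = mpp
        ecc = 0.0
    bbox_px = (region.bbox[2] - region.bbox[0]) * (region.bbox[3] - region.bbox[1])
    return {
        "area_px": int(area_px),
        "area_um2": area_px * mpp * mpp,
        "extent": area_px / bbox_px,
        "equiv_diameter_um": float(np.sqrt(4.0 * area_px / np.pi)) * mpp,
        "eccentricity": float(ecc),
        "convex_area_um2": float(region.area_convex) * mpp * mpp,
        "major_axis_um": float(mjl),
        "minor_axis_um": float(mnl),
        "bbox_area_um2": bbox_px * mpp * mpp,
    }


def nucleus_features(mask: np.ndarray, mpp: float) -> dict:
    """Shape descriptors for a single nucleus given its boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    region = regionprops(mask.astype(np.uint8))[0]
    row = _shape_row(region, mpp)
    cr, cc = region.centroid
    row["centre_row"], row["centre_col"] = float(cr), float(cc)
    return row


def assign_compartment(coords: np.ndarray, layer_mask: np.ndarray) -> str:
    """Majority layer label over the nucleus's pixels.

    Ties are broken by the layer under the area centroid (nearest pixel);
    a nucleus over pure background maps to ``"background"``.
    """
    labels = layer_mask[coords[:, 0], coords[:, 1]]
    vals, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    if winners.size > 1:
        # nearest pixel to the area centroid, half rounded up
        cr = int(np.clip(np.floor(coords[:, 0].mean() + 0.5), 0, layer_mask.shape[0] - 1))
        cc = int(np.clip(np.floor(coords[:, 1].mean() + 0.5), 0, layer_mask.shape[1] - 1))
        centre_label = layer_mask[cr, cc]
        winner = centre_label if centre_label in winners else winners[0]
    else:
        winner = winners[0]
    return LAYER_NAMES[TissueLayer(int(winner))]


def nucleus_feature_table(slide: SlideRaster) -> pd.DataFrame:
    """Per-nucleus features for every instance on a slide.

    Returns one row per instance id with shape descriptors, the nuclear
    class (majority class-map code over the instance, which is uniform for
    well-formed inputs) and the tissue compartment by majority layer.
    """
    rows = []
    for region in regionprops(slide.instance_map):
        row = {"id": int(region.label)}
        row.update(_shape_row(region, slide.mpp))
        cr, cc = region.centroid
        row["centre_row"], row["centre_col"] = float(cr), float(cc)
        coords = region.coords
        cls_codes = slide.class_map[coords[:, 0], coords[:, 1]]
        vals, counts = np.unique(cls_codes, return_counts=True)
        row["class"] = NucleusClass(int(vals[np.argmax(counts)])).name.lower()
        row["compartment"] = assign_compartment(coords, slide.layer_mask)
        rows.append(row)
    cols = [
        "id", "class", "compartment", "centre_row", "centre_col", "area_px",
        *SHAPE_FEATURES,
    ]
    return pd.DataFrame(rows, columns=cols)


def nearest_neighbour_distances(centroids: np.ndarray, mpp: float) -> np.ndarray:
    """Per-nucleus distance (um) to the nearest other centroid.

    NaN when fewer than two centroids are supplied.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n < 2:
        return np.full(n, np.nan)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1] * mpp


def local_density_counts(
    centroids: np.ndarray, mpp: float, radius_um: float = 100.0
) -> np.ndarray:
    """Number of *other* centroids within ``radius_um`` of each centroid."""
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius_um / mpp, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # exclude self


def _compartment_areas(layer_mask: np.ndarray, mpp: float) -> dict[str, float]:
    return {
        name: float(np.count_nonzero(layer_mask == LAYER_BY_NAME[name])) * mpp * mpp
        for name in COMPARTMENTS
    }


def aggregate_patch(
    nuclei: pd.DataFrame,
    compartment_areas_um2: dict[str, float],
    features: tuple[str, ...] = MORPHOMETRIC_FEATURES,
) -> pd.Series:
    """Per-compartment counts, cellularity and feature statistics.

    For each compartment c the output holds ``{c}_nc`` (count), ``{c}_phi``
    (nuclei per um^2 of compartment area, NaN when the compartment has zero
    area) and ``{c}_{stat}_{feature}`` for stat in min/max/mean/median/std.
    Statistics are NaN when undefined (no nuclei; std needs >= 2).  The
    sample (n-1) standard deviation is used.
    """
    out: dict[str, float] = {}
    for comp in COMPARTMENTS:
        sub = nuclei[nuclei["compartment"] == comp] if len(nuclei) else nuclei
        nc = len(sub)
        out[f"{comp}_nc"] = nc
        area = compartment_areas_um2.get(comp, 0.0)
        if area > 0:
            out[f"{comp}_phi"] = nc / area
        else:
            if nc:
                warnings.warn(f"compartment {comp} has zero area; phi undefined", stacklevel=2)
            out[f"{comp}_phi"] = np.nan
        for feat in features:
            vals = sub[feat].to_numpy(dtype=float) if nc else np.array([])
            vals = vals[np.isfinite(vals)]
            m = len(vals)
            out[f"{comp}_min_{feat}"] = vals.min() if m else np.nan
            out[f"{comp}_max_{feat}"] = vals.max() if m else np.nan
            out[f"{comp}_mean_{feat}"] = vals.mean() if m else np.nan
            out[f"{comp}_median_{feat}"] = float(np.median(vals)) if m else np.nan
            out[f"{comp}_std_{feat}"] = vals.std(ddof=1) if m >= 2 else np.nan
    return pd.Series(out)


def compute_patch_features(
    nuclei: pd.DataFrame,
    layer_mask: np.ndarray,
    windows: list[PatchWindow],
    mpp: float,
) -> pd.DataFrame:
    """Aggregate nucleus features over each patch window.

    Nuclei belong to the patch whose window contains their centroid;
    proximity features (NND, 100 um counts) are recomputed within each
    patch and compartment before aggregation.  Also reports total nucleus
    count and the inflammatory-in-connective (PEL) count per patch.
    """
    rows = []
    for wdw in windows:
        sub = nuclei_in_window(nuclei, wdw).copy()
        for comp, grp in sub.groupby("compartment"):
            pts = grp[["centre_row", "centre_col"]].to_numpy()
            sub.loc[grp.index, "nnd_um"] = nearest_neighbour_distances(pts, mpp)
            sub.loc[grp.index, "count_100um"] = local_density_counts(pts, mpp)
        if "nnd_um" not in sub.columns:
            sub["nnd_um"] = np.nan
            sub["count_100um"] = np.nan
        crop = layer_mask[wdw.row0 : wdw.row0 + wdw.rows, wdw.col0 : wdw.col0 + wdw.cols]
        areas = _compartment_areas(crop, mpp)
        row = aggregate_patch(sub, areas)
        row["slide_id"] = wdw.slide_id
        row["patch_index"] = wdw.index
        row["total_nc"] = len(sub)
        row["pel_count"] = int(
            ((sub["class"] == "inflammatory") & (sub["compartment"] == "connective_tissue")).sum()
        )
        row["pel_ratio"] = row["pel_count"] / row["total_nc"] if row["total_nc"] else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        lead = ["slide_id", "patch_index", "total_nc", "pel_count", "pel_ratio"]
        df = df[lead + [c for c in df.columns if c not in lead]]
        df["slide_id"] = df["slide_id"].astype(int)
        df["patch_index"] = df["patch_index"].astype(int)
    return df
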