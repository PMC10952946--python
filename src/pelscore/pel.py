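"""Peri-epithelial lymphocyte (PEL) scoring and hotspot tile selection.

The PEL score of a patch is the number of inflammatory-class nuclei whose
compartment is connective tissue; because patches are anchored on the
epithelium, that connective tissue is peri-epithelial by construction.
Hotspots / coldspots are the k highest- / lowest-scoring tiles of a
slide's transformation-probability heatmap; slide-level features for
survival are statistical aggregates of patch features over a tile set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HotspotConfig",
    "patch_pel",
    "select_tiles",
    "aggregate_slide",
    "slide_feature_table",
]

AGGREGATORS = {
    "min": np.nanmin,
    "max": np.nanmax,
    "mean": np.nanmean,
    "median": np.nanmedian,
    "std": lambda v: np.nanstd(v, ddof=1),
}


@dataclass(frozen=True)
class HotspotConfig:
    """Number of top / bottom heatmap tiles kept per slide (default 5)."""

    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def patch_pel(patch_nuclei: pd.DataFrame) -> tuple[int, float]:
    """PEL count and ratio for one patch's nucleus table.

    count = inflammatory nuclei in connective tissue; ratio = count over
    all nuclei in the patch (0 when the patch has no nuclei).
    """
    total = len(patch_nuclei)
    count = int(
        (
            (patch_nuclei["class"] == "inflammatory")
            & (patch_nuclei["compartment"] == "connective_tissue")
        ).sum()
    )
    return count, (count / total if total else 0.0)


def select_tiles(
    scores, config: HotspotConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """k highest- and k lowest-scoring patch indices of one slide.

    ``scores`` is a mapping/Series from patch index to heatmap score.  If
    fewer than k patches exist, all patches are both hotspot and coldspot.
    Score ties are broken by ascending patch index.
    """
    config = config or HotspotConfig()
    s = pd.Series(scores)
    if s.empty:
        raise ValueError("empty heatmap: no scored patches")
    idx = s.index.to_numpy()
    vals = s.to_numpy(dtype=float)
    if len(s) <= config.k:
        both = idx[np.argsort(idx)]
        return both.copy(), both.copy()
    hot_order = np.lexsort((idx, -vals))
    cold_order = np.lexsort((idx, vals))
    return idx[hot_order[: config.k]], idx[cold_order[: config.k]]


def aggregate_slide(
    patch_values: pd.DataFrame,
    aggregators: tuple[str, ...] = ("min", "max", "mean", "median", "std"),
) -> pd.Series:
    """Apply aggregators column-wise over a tile set's patch features.

    Missing patch values are excluded; a feature missing on every tile
    aggregates to NaN with a warning.  Output keys are ``{agg}_{feature}``.
    """
    if patch_values.empty:
        raise ValueError("tile set is empty")
    out: dict[str, float] = {}
    all_missing: list[str] = []
    for col in patch_values.columns:
        vals = patch_values[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            all_missing.append(col)
        for agg in aggregators:
            if finite.size == 0 or (agg == "std" and finite.size < 2):
                out[f"{agg}_{col}"] = np.nan
            else:
                out[f"{agg}_{col}"] = float(AGGREGATORS[agg](finite))
    if all_missing:
        warnings.warn(
            f"{len(all_missing)} feature(s) missing on all selected tiles "
            f"(e.g. {all_missing[0]})",
            stacklevel=2,
        )
    return pd.Series(out)


def slide_feature_table(
    patch_features: pd.DataFrame,
    heatmaps: pd.DataFrame,
    config: HotspotConfig | None = None,
    tiles: str = "hotspot",
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Slide-level feature table over a tile set for every slide.

    ``tiles`` selects which patches feed the aggregation: ``"hotspot"``
    (default, per the prognostic workflow), ``"coldspot"`` or ``"all"``.
    ``patch_features`` and ``heatmaps`` must share slide_id / patch_index
    keys.
    """
    config = config or HotspotConfig()
    if tiles not in ("hotspot", "coldspot", "all"):
        raise ValueError("tiles must be 'hotspot', 'coldspot' or 'all'")
    drop = {"slide_id", "patch_index"}
    feats = feature_columns or [c for c in patch_features.columns if c not in drop]
    rows = []
    for sid, grp in patch_features.groupby("slide_id"):
        grp = grp.set_index("patch_index")
        if tiles == "all":
            chosen = grp.index.to_numpy()
        else:
            hm = heatmaps[heatmaps["slide_id"] == sid].set_index("patch_index")["score"]
            hm = hm.loc[hm.index.intersection(grp.index)]
            if hm.empty:
                continue
            hot, cold = select_tiles(hm, config)
            chosen = hot if tiles == "hotspot" else cold
        row = aggregate_slide(grp.loc[chosen, feats])
        row["slide_id"] = sid
        row["n_tiles"] = len(chosen)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df["slide_id"] = df["slide_id"].astype(int)
        df["n_tiles"] = df["n_tiles"].astype(int)
        lead = ["slide_id", "n_tiles"]
        df = df[lead + [c for c in df.columns if c not in lead]]
    return df.reset_index(drop=True)
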