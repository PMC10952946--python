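"""End-to-end orchestration: cohort -> patches -> morphometry -> PEL
scoring -> slide feature table ready for association / survival /
evaluation.
"""

from __future__ import annotations

import pandas as pd

from .morphometry import compute_patch_features, nucleus_feature_table
from .patching import PatchingConfig, extract_patch_grid
from .pel import HotspotConfig, slide_feature_table
from .synthetic import Cohort

__all__ = ["cohort_patch_features", "cohort_slide_features", "analysis_table"]


def cohort_patch_features(
    cohort: Cohort, patching: PatchingConfig | None = None
) -> pd.DataFrame:
    """Per-patch aggregated nuclear features for every slide, computed
    from the rasters (not the generator truth tables)."""
    patching = patching or PatchingConfig()
    frames = []
    for i, slide in enumerate(cohort.slides):
        nuclei = nucleus_feature_table(slide)
        windows = extract_patch_grid(slide.layer_mask, patching, slide_id=i)
        if not windows:
            continue
        frames.append(compute_patch_features(nuclei, slide.layer_mask, windows, slide.mpp))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def cohort_slide_features(
    cohort: Cohort,
    patching: PatchingConfig | None = None,
    hotspots: HotspotConfig | None = None,
    tiles: str = "hotspot",
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Slide-level feature table over the selected tile set."""
    patch_features = cohort_patch_features(cohort, patching)
    return slide_feature_table(
        patch_features, cohort.heatmaps, hotspots, tiles, feature_columns
    )


def analysis_table(
    slide_features: pd.DataFrame,
    clinical: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> pd.DataFrame:
    """Join slide features with clinical covariates and outcomes, adding
    the binary indicators used by the survival harness."""
    df = slide_features.merge(clinical, on="slide_id").merge(
        outcomes[["slide_id", "event", "time"]], on="slide_id"
    )
    df["male"] = (df["gender"] == "male").astype(int)
    df["high_risk_grade"] = (df["binary_grade"] == "high_risk").astype(int)
    df["who_moderate_severe"] = df["who_grade"].isin(["moderate", "severe"]).astype(int)
    df["who_severe"] = (df["who_grade"] == "severe").astype(int)
    return df
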