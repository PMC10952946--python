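"""Synthetic OED cohort generator.

Real inputs to the scoring pipeline are private whole-slide images run
through upstream nuclear segmentation / layer segmentation networks.  This
module emulates those *outputs* directly: per-slide label maps with a
layered epithelium (keratin / epithelial / basal bands over connective
tissue), elliptical nuclei with class-dependent shape distributions placed
by hard-core rejection, per-patch transformation-probability heatmaps
coupled to local composition, clinical covariates, and exponential
time-to-transformation outcomes whose hazard is coupled to peri-epithelial
lymphocyte (PEL) density and layer nuclei counts.

Two generation routes are provided:

``generate_cohort``
    full raster route — renders label maps so that patching, morphometry
    and scoring can be exercised end to end;
``simulate_feature_cohort``
    raster-free route — draws the same per-slide / per-patch count
    statistics directly, for power and calibration studies where rendering
    thousands of slides would be wasteful.

All randomness flows from a single seeded root generator with per-slide
substreams (``numpy.random.SeedSequence.spawn``), so a cohort is
reproducible and individual slides can be regenerated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .labels import CLASS_NAMES, LAYER_NAMES, NucleusClass, TissueLayer

__all__ = [
    "NucleusShape",
    "CohortConfig",
    "SlideRaster",
    "Cohort",
    "render_slide",
    "simulate_outcomes",
    "simulate_heatmap",
    "generate_cohort",
    "simulate_feature_cohort",
]


@dataclass(frozen=True)
class NucleusShape:
    """Ellipse shape distribution for one nuclear class.

    ``major_um`` is the mean full major-axis length in microns;
    ``axis_ratio`` the mean minor/major ratio.  Orientations are uniform.
    """

    major_um: float
    major_sd: float
    axis_ratio: float
    ratio_sd: float


@dataclass(frozen=True)
class SlideRaster:
    """Bundled label maps for one slide.

    instance_map : int32, 0 = background, i > 0 = nucleus i
    class_map    : uint8 ``NucleusClass`` codes, nonzero exactly where
                   ``instance_map`` is nonzero
    layer_mask   : uint8 ``TissueLayer`` codes
    mpp          : microns per pixel
    """

    instance_map: np.ndarray
    class_map: np.ndarray
    layer_mask: np.ndarray
    mpp: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.instance_map.shape


# Table-1-like marginal frequencies used for the clinical table.
_SITE_NAMES = ("tongue", "floor_of_mouth", "buccal_mucosa", "other")
_SITE_PROBS = (0.386, 0.197, 0.124, 0.293)
_MALE_FRACTION = 0.613
_WHO_FRACTIONS = (0.299, 0.386, 0.315)  # mild, moderate, severe
_LOW_RISK_FRACTION = 0.583


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one synthetic cohort.

    Densities are nuclei per 10^4 um^2 of compartment area.  The hazard
    model is exponential with rate ``h0 * exp(eta)`` where
    ``eta = beta . z(PEL density, epithelial NC, basal NC)``; follow-up is
    administratively censored at ``censor_time`` years.  The defaults are
    calibrated so the marginal cohort (risk-score spread included) has an
    event fraction near 36% and a mean observed transformation time near
    6.5 years.
    """

    n_slides: int = 60
    slide_size_px: tuple[int, int] = (1024, 1024)
    mpp: float = 0.50
    # keratin, epithelial, basal, connective fractions of tissue height
    layer_band_fractions: tuple[float, float, float, float] = (0.10, 0.40, 0.15, 0.35)
    nucleus_shape_params: dict[str, NucleusShape] = field(
        default_factory=lambda: {
            "epithelial": NucleusShape(9.0, 1.2, 0.70, 0.08),
            "inflammatory": NucleusShape(6.0, 0.6, 0.90, 0.05),
            "connective": NucleusShape(10.0, 1.5, 0.45, 0.08),
            "other": NucleusShape(8.0, 1.0, 0.70, 0.10),
        }
    )
    # structural nuclei per 10^4 um^2 per compartment
    density_params: dict[str, float] = field(
        default_factory=lambda: {
            "keratin": 3.0,
            "epithelial": 45.0,
            "basal": 65.0,
            "connective_tissue": 12.0,
        }
    )
    # slide-level inflammatory intensity in connective tissue, per 10^4 um^2
    lambda_pel_range: tuple[float, float] = (2.0, 30.0)
    # log-hazard effects of z-scored (PEL density, epithelial NC, basal NC)
    beta: tuple[float, float, float] = (0.7, 0.3, 0.3)
    h0: float = 0.026  # baseline events per year
    censor_time: float = 15.0  # years
    heatmap_coeffs: tuple[float, float, float] = (1.5, 0.8, 0.25)  # a, b, noise_sd
    seed: int = 0

    def validate(self) -> None:
        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        if any(s < 1 for s in self.slide_size_px):
            raise ValueError("slide_size_px entries must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if abs(sum(self.layer_band_fractions) - 1.0) > 1e-9:
            raise ValueError("layer_band_fractions must sum to 1")
        if any(f <= 0 for f in self.layer_band_fractions):
            raise ValueError("layer_band_fractions must be positive")
        if any(d < 0 for d in self.density_params.values()):
            raise ValueError("density_params must be non-negative")
        lo, hi = self.lambda_pel_range
        if lo < 0 or hi < lo:
            raise ValueError("lambda_pel_range must satisfy 0 <= lo <= hi")
        if self.h0 <= 0:
            raise ValueError("h0 must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.heatmap_coeffs[2] < 0:
            raise ValueError("heatmap_coeffs noise_sd must be non-negative")


@dataclass
class Cohort:
    """Everything ``generate_cohort`` produces."""

    slides: list[SlideRaster]
    truths: list[pd.DataFrame]
    clinical: pd.DataFrame
    outcomes: pd.DataFrame
    heatmaps: pd.DataFrame  # slide_id, patch_index, row0, col0, score
    slide_features: pd.DataFrame  # truth-derived slide-level covariates


# ---------------------------------------------------------------------------
# layer geometry
# ---------------------------------------------------------------------------

def _layer_mask(shape: tuple[int, int], fractions, rng: np.random.Generator) -> np.ndarray:
    """Horizontal bands with a low-frequency sinusoidal boundary wobble.

    Wobble amplitude is capped at 8% of the smaller adjacent band height so
    band ordering is preserved while boundary tie cases still occur.
    """
    h, w = shape
    cum = np.cumsum(fractions)[:3]  # keratin|epithelial, epith|basal, basal|conn
    cols = np.arange(w)
    boundaries = []
    for i, c in enumerate(cum):
        adjacent = min(fractions[i], fractions[i + 1])
        amp = 0.08 * adjacent * h
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        b = c * h + amp * np.sin(2 * np.pi * freq * cols / w + phase)
        boundaries.append(b)
    rows = np.arange(h)[:, None]
    mask = np.full(shape, TissueLayer.CONNECTIVE_TISSUE, dtype=np.uint8)
    mask[rows < boundaries[2]] = TissueLayer.BASAL
    mask[rows < boundaries[1]] = TissueLayer.EPITHELIAL
    mask[rows < boundaries[0]] = TissueLayer.KERATIN
    return mask


# compartment -> nuclear class for structural (non-inflammatory) nuclei
_STRUCTURAL_CLASS = {
    TissueLayer.KERATIN: NucleusClass.EPITHELIAL,
    TissueLayer.EPITHELIAL: NucleusClass.EPITHELIAL,
    TissueLayer.BASAL: NucleusClass.EPITHELIAL,
    TissueLayer.CONNECTIVE_TISSUE: NucleusClass.CONNECTIVE,
}


def render_slide(
    config: CohortConfig,
    lambda_pel: float,
    rng: np.random.Generator,
) -> tuple[SlideRaster, pd.DataFrame]:
    """Render one slide's label maps and its nucleus ground-truth table.

    Nuclei are rasterised ellipses placed by hard-core rejection on pixels
    (a candidate overlapping an existing nucleus is redrawn, up to a
    bounded number of retries); unplaceable nuclei are dropped with a
    warning rather than silently.  A nucleus's recorded compartment is the
    majority layer label under its pixels; candidates whose majority layer
    disagrees with the layer under their centre are rejected so both
    conventions agree on generated truth.
    """
    config.validate()
    shape = config.slide_size_px
    mpp = config.mpp
    layer = _layer_mask(shape, config.layer_band_fractions, rng)
    instance = np.zeros(shape, dtype=np.int32)
    classes = np.zeros(shape, dtype=np.uint8)

    px_area_um2 = mpp * mpp
    # requested nucleus counts per (compartment, class)
    requests: list[tuple[TissueLayer, NucleusClass, int]] = []
    for comp in (
        TissueLayer.KERATIN,
        TissueLayer.EPITHELIAL,
        TissueLayer.BASAL,
        TissueLayer.CONNECTIVE_TISSUE,
    ):
        area_um2 = np.count_nonzero(layer == comp) * px_area_um2
        dens = config.density_params[LAYER_NAMES[comp]]
        n = rng.poisson(dens * area_um2 / 1e4)
        if n:
            requests.append((comp, _STRUCTURAL_CLASS[comp], int(n)))
        if comp is TissueLayer.CONNECTIVE_TISSUE and lambda_pel > 0:
            n_pel = rng.poisson(lambda_pel * area_um2 / 1e4)
            if n_pel:
                requests.append((comp, NucleusClass.INFLAMMATORY, int(n_pel)))

    comp_pixels = {
        comp: np.flatnonzero(layer == comp)
        for comp in (
            TissueLayer.KERATIN,
            TissueLayer.EPITHELIAL,
            TissueLayer.BASAL,
            TissueLayer.CONNECTIVE_TISSUE,
        )
    }
    w = shape[1]
    rows_out: list[dict] = []
    next_id = 1
    dropped = 0
    for comp, ncls, n in requests:
        flat = comp_pixels[comp]
        if flat.size == 0:
            dropped += n
            continue
        shp = config.nucleus_shape_params[CLASS_NAMES[ncls]]
        for _ in range(n):
            placed = False
            for _attempt in range(30):
                idx = flat[rng.integers(flat.size)]
                r0, c0 = idx // w, idx % w
                major = max(rng.normal(shp.major_um, shp.major_sd), 2.0 * mpp)
                ratio = float(np.clip(rng.normal(shp.axis_ratio, shp.ratio_sd), 0.2, 1.0))
                a_px = max(major / (2.0 * mpp), 1.0)  # semi-major in px
                b_px = max(a_px * ratio, 1.0)
                theta = rng.uniform(0, np.pi)
                rr, cc = draw_ellipse(r0, c0, a_px, b_px, shape=shape, rotation=theta)
                if rr.size == 0:
                    continue
                # reject clipped (out-of-raster) ellipses: keep nuclei whole
                if rr.min() == 0 or cc.min() == 0 or rr.max() == shape[0] - 1 or cc.max() == shape[1] - 1:
                    full_area = np.pi * a_px * b_px
                    if rr.size < 0.95 * full_area:
                        continue
                if instance[rr, cc].any():
                    continue
                labels, counts = np.unique(layer[rr, cc], return_counts=True)
                majority = labels[np.argmax(counts)]
                if majority != comp or layer[r0, c0] != comp:
                    continue
                instance[rr, cc] = next_id
                classes[rr, cc] = ncls
                rows_out.append(
                    {
                        "id": next_id,
                        "class": CLASS_NAMES[ncls],
                        "compartment": LAYER_NAMES[comp],
                        "centre_row": float(rr.mean()),
                        "centre_col": float(cc.mean()),
                        "semi_major_um": a_px * mpp,
                        "semi_minor_um": b_px * mpp,
                        "orientation_rad": theta,
                    }
                )
                next_id += 1
                placed = True
                break
            if not placed:
                dropped += 1
    if dropped:
        warnings.warn(
            f"hard-core placement dropped {dropped} nuclei after bounded retries",
            stacklevel=2,
        )
    truth = pd.DataFrame(
        rows_out,
        columns=[
            "id",
            "class",
            "compartment",
            "centre_row",
            "centre_col",
            "semi_major_um",
            "semi_minor_um",
            "orientation_rad",
        ],
    )
    return SlideRaster(instance, classes, layer, mpp), truth


# ---------------------------------------------------------------------------
# outcomes & heatmaps
# ---------------------------------------------------------------------------

def simulate_outcomes(
    risk_scores: np.ndarray,
    h0: float,
    censor_time: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Exponential proportional-hazards outcomes with administrative censoring.

    Event time E_i ~ Exponential(rate = h0 * exp(eta_i)); the observed time
    is min(E_i, censor_time) and event_i = 1 iff E_i <= censor_time.
    """
    eta = np.asarray(risk_scores, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("risk scores must be finite")
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    if censor_time <= 0:
        raise ValueError("censor_time must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rate = h0 * np.exp(eta)
    e = rng.exponential(1.0 / rate)
    time = np.minimum(e, censor_time)
    event = (e <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "slide_id": np.arange(eta.size),
            "event": event,
            "time": time,
            "risk_score": eta,
        }
    )


def simulate_heatmap(
    patch_features: pd.DataFrame,
    coeffs: tuple[float, float, float],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Per-patch transformation probabilities coupled to composition.

    score = logistic(a * z(PEL count) + b * z(total NC) + eps),
    eps ~ Normal(0, noise_sd); z-scores are taken over the supplied patch
    set (constant columns z to zero).
    """
    a, b, noise_sd = coeffs
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pel = np.asarray(patch_features["pel_count"], dtype=float)
    nc = np.asarray(patch_features["total_nc"], dtype=float)
    if not (np.all(np.isfinite(pel)) and np.all(np.isfinite(nc))):
        raise ValueError("patch features must be finite")

    def _z(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    lin = a * _z(pel) + b * _z(nc)
    if noise_sd > 0:
        lin = lin + rng.normal(0.0, noise_sd, size=lin.size)
    return 1.0 / (1.0 + np.exp(-lin))


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else np.zeros_like(v, dtype=float)


def _clinical_table(eta: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates; grades are thresholded noisy copies of eta so
    grading correlates with outcome, as grading is prognostic in practice."""
    n = eta.size
    age = np.clip(np.round(rng.normal(64.6, 14.0, n)), 25, 97).astype(int)
    gender = np.where(rng.random(n) < _MALE_FRACTION, "male", "female")
    site = rng.choice(_SITE_NAMES, size=n, p=np.array(_SITE_PROBS) / sum(_SITE_PROBS))
    noisy = _zscore(eta) + rng.normal(0.0, 1.0, n)
    order = np.argsort(np.argsort(noisy))  # ranks 0..n-1
    q = (order + 0.5) / n
    who = np.where(
        q < _WHO_FRACTIONS[0], "mild", np.where(q < _WHO_FRACTIONS[0] + _WHO_FRACTIONS[1], "moderate", "severe")
    )
    noisy2 = _zscore(eta) + rng.normal(0.0, 1.0, n)
    q2 = (np.argsort(np.argsort(noisy2)) + 0.5) / n
    binary = np.where(q2 < _LOW_RISK_FRACTION, "low_risk", "high_risk")
    return pd.DataFrame(
        {
            "slide_id": np.arange(n),
            "age": age,
            "gender": gender,
            "site": site,
            "who_grade": who,
            "binary_grade": binary,
        }
    )


def _slide_truth_features(truth: pd.DataFrame, slide: SlideRaster) -> dict:
    """Truth-derived slide covariates that drive the hazard."""
    conn_area_um2 = (
        np.count_nonzero(slide.layer_mask == TissueLayer.CONNECTIVE_TISSUE)
        * slide.mpp ** 2
    )
    pel = int(
        (
            (truth["class"] == "inflammatory")
            & (truth["compartment"] == "connective_tissue")
        ).sum()
    )
    return {
        "pel_count": pel,
        "pel_density": pel / conn_area_um2 * 1e4 if conn_area_um2 > 0 else 0.0,
        "epithelial_nc": int((truth["compartment"] == "epithelial").sum()),
        "basal_nc": int((truth["compartment"] == "basal").sum()),
    }


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (rasters, truth, clinical, outcomes,
    heatmaps).

    Heatmaps are computed on the default 512 px / 50%-overlap patch grid
    over the slide's epithelium; per-patch PEL and total nucleus counts for
    the heatmap coupling come from the truth tables (centroid-in-window).
    """
    config.validate()
    # local import: patching depends only on labels, no cycle at runtime
    from .patching import PatchingConfig, extract_patch_grid

    root = np.random.SeedSequence(config.seed)
    slide_seeds = root.spawn(config.n_slides)
    tail = root.spawn(4)
    lam_rng = np.random.default_rng(tail[0])
    lo, hi = config.lambda_pel_range
    lambdas = lam_rng.uniform(lo, hi, config.n_slides)

    slides: list[SlideRaster] = []
    truths: list[pd.DataFrame] = []
    feat_rows = []
    for i in range(config.n_slides):
        rng = np.random.default_rng(slide_seeds[i])
        slide, truth = render_slide(config, lambdas[i], rng)
        slides.append(slide)
        truths.append(truth)
        row = {"slide_id": i, "lambda_pel": lambdas[i]}
        row.update(_slide_truth_features(truth, slide))
        feat_rows.append(row)
    slide_features = pd.DataFrame(feat_rows)

    beta = np.asarray(config.beta, dtype=float)
    z = np.column_stack(
        [
            _zscore(slide_features["pel_density"].to_numpy(dtype=float)),
            _zscore(slide_features["epithelial_nc"].to_numpy(dtype=float)),
            _zscore(slide_features["basal_nc"].to_numpy(dtype=float)),
        ]
    )
    eta = z @ beta
    outcomes = simulate_outcomes(
        eta, config.h0, config.censor_time, np.random.default_rng(tail[1])
    )
    clinical = _clinical_table(eta, np.random.default_rng(tail[2]))

    hm_rng = np.random.default_rng(tail[3])
    pcfg = PatchingConfig()
    hm_rows = []
    for i, (slide, truth) in enumerate(zip(slides, truths)):
        windows = extract_patch_grid(slide.layer_mask, pcfg, slide_id=i)
        if not windows:
            continue
        counts = []
        for wdw in windows:
            inside = (
                (truth["centre_row"] >= wdw.row0)
                & (truth["centre_row"] < wdw.row0 + wdw.rows)
                & (truth["centre_col"] >= wdw.col0)
                & (truth["centre_col"] < wdw.col0 + wdw.cols)
            )
            sub = truth[inside]
            counts.append(
                {
                    "pel_count": int(
                        (
                            (sub["class"] == "inflammatory")
                            & (sub["compartment"] == "connective_tissue")
                        ).sum()
                    ),
                    "total_nc": len(sub),
                }
            )
        cdf = pd.DataFrame(counts)
        scores = simulate_heatmap(cdf, config.heatmap_coeffs, hm_rng)
        for wdw, s in zip(windows, scores):
            hm_rows.append(
                {
                    "slide_id": i,
                    "patch_index": wdw.index,
                    "row0": wdw.row0,
                    "col0": wdw.col0,
                    "score": float(s),
                }
            )
    heatmaps = pd.DataFrame(
        hm_rows, columns=["slide_id", "patch_index", "row0", "col0", "score"]
    )
    return Cohort(slides, truths, clinical, outcomes, heatmaps, slide_features)


# ---------------------------------------------------------------------------
# raster-free statistical twin
# ---------------------------------------------------------------------------

def simulate_feature_cohort(
    config: CohortConfig,
    n_patches: int = 9,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Draw the cohort's count statistics directly, skipping rasterisation.

    Mirrors the raster route: per-slide PEL intensity uniform over
    ``lambda_pel_range``; per-patch structural counts Poisson around
    layer-density expectations with a lognormal between-slide multiplier
    (CV ~ 0.15) standing in for epithelium-geometry variation; hazards
    coupled to z-scored slide totals through ``config.beta``; heatmaps via
    :func:`simulate_heatmap` per slide.

    Returns a dict with ``patch_features``, ``slide_features``,
    ``heatmaps``, ``clinical`` and ``outcomes`` frames.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_lam, s_counts, s_hm, s_out, s_clin = root.spawn(5)
    rng_lam = np.random.default_rng(s_lam)
    rng_cnt = np.random.default_rng(s_counts)
    rng_hm = np.random.default_rng(s_hm)

    n = config.n_slides
    h_px, w_px = config.slide_size_px
    slide_area_um2 = h_px * w_px * config.mpp ** 2
    fr = config.layer_band_fractions
    area = {
        "keratin": slide_area_um2 * fr[0],
        "epithelial": slide_area_um2 * fr[1],
        "basal": slide_area_um2 * fr[2],
        "connective_tissue": slide_area_um2 * fr[3],
    }
    # per-patch share of each compartment (patches tile the epithelium)
    patch_share = {k: v / n_patches for k, v in area.items()}

    lo, hi = config.lambda_pel_range
    lambdas = rng_lam.uniform(lo, hi, n)
    mult = np.exp(rng_cnt.normal(0.0, 0.15, size=(n, 3)))  # epi, basal, conn

    patch_rows = []
    hm_rows = []
    for i in range(n):
        epi_rate = config.density_params["epithelial"] * patch_share["epithelial"] / 1e4 * mult[i, 0]
        bas_rate = config.density_params["basal"] * patch_share["basal"] / 1e4 * mult[i, 1]
        con_rate = config.density_params["connective_tissue"] * patch_share["connective_tissue"] / 1e4 * mult[i, 2]
        pel_rate = lambdas[i] * patch_share["connective_tissue"] / 1e4
        epi = rng_cnt.poisson(epi_rate, n_patches)
        bas = rng_cnt.poisson(bas_rate, n_patches)
        con = rng_cnt.poisson(con_rate, n_patches)
        pel = rng_cnt.poisson(pel_rate, n_patches)
        total = epi + bas + con + pel
        for j in range(n_patches):
            patch_rows.append(
                {
                    "slide_id": i,
                    "patch_index": j,
                    "pel_count": int(pel[j]),
                    "epithelial_nc": int(epi[j]),
                    "basal_nc": int(bas[j]),
                    "connective_nc": int(con[j]),
                    "total_nc": int(total[j]),
                    "pel_ratio": float(pel[j] / total[j]) if total[j] else 0.0,
                }
            )
        cdf = pd.DataFrame({"pel_count": pel, "total_nc": total})
        scores = simulate_heatmap(cdf, config.heatmap_coeffs, rng_hm)
        for j, s in enumerate(scores):
            hm_rows.append({"slide_id": i, "patch_index": j, "score": float(s)})

    patch_features = pd.DataFrame(patch_rows)
    heatmaps = pd.DataFrame(hm_rows)
    agg = patch_features.groupby("slide_id").agg(
        pel_count=("pel_count", "sum"),
        epithelial_nc=("epithelial_nc", "sum"),
        basal_nc=("basal_nc", "sum"),
    )
    slide_features = agg.reset_index()
    slide_features["lambda_pel"] = lambdas
    slide_features["pel_density"] = slide_features["pel_count"] / area["connective_tissue"] * 1e4

    beta = np.asarray(config.beta, dtype=float)
    z = np.column_stack(
        [
            _zscore(slide_features["pel_density"].to_numpy(dtype=float)),
            _zscore(slide_features["epithelial_nc"].to_numpy(dtype=float)),
            _zscore(slide_features["basal_nc"].to_numpy(dtype=float)),
        ]
    )
    eta = z @ beta
    outcomes = simulate_outcomes(
        eta, config.h0, config.censor_time, np.random.default_rng(s_out)
    )
    clinical = _clinical_table(eta, np.random.default_rng(s_clin))
    return {
        "patch_features": patch_features,
        "slide_features": slide_features,
        "heatmaps": heatmaps,
        "clinical": clinical,
        "outcomes": outcomes,
    }
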