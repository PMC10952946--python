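# Methods

`pelscore` implements a digital prognostic pipeline for oral epithelial
dysplasia (OED): starting from per-slide nuclear label maps and an
intra-epithelial layer mask, it computes layer-wise nuclear morphometrics,
scores peri-epithelial lymphocytes (PELs) over heatmap-selected hotspot
tiles, and runs the downstream association and progression-free-survival
(PFS) analyses.  Because the clinical whole-slide cohorts such a pipeline
consumes are private, the package ships a synthetic cohort generator with
the statistical structure the analyses assume, so every stage is testable
end to end.

## Pipeline model

**Inputs per slide.** Three aligned rasters at a stated resolution (mpp,
microns per pixel; default 0.50): an instance map (0 = background, i > 0 =
nucleus i), a nuclear class map (epithelial / inflammatory / connective /
other — the output contract of a HoVer-Net-style segmenter), and a layer
mask (keratin / epithelial / basal / connective tissue — the output
contract of an intra-epithelial layer segmenter).  Additionally a
per-patch transformation-probability heatmap (e.g. from a weakly
supervised classifier) and a clinical table (age, gender, site, WHO and
binary grade, transformation status, follow-up time).

**Tiling.** 512×512 px tiles at 50% overlap are enumerated row-major from
the raster origin; a tile is retained iff its epithelium fraction
(keratin ∪ epithelial ∪ basal) is ≥ θ.  θ is not a published constant;
the default 0.2 is deliberately permissive so retained tiles also contain
adjacent connective tissue, which the PEL score needs.  Windows are
half-open, 0-based, and never padded.  A nucleus belongs to the tile
containing its area centroid, which prevents double counting across
overlapping tiles.

**Morphometry.** Per nucleus: area, extent (area / bounding-box area),
equivalent diameter √(4·area/π), eccentricity and major/minor axis
lengths from the ellipse with matching second central moments, convex
area, bounding-box area — standard regionprops definitions, with lengths
converted to microns so features are scanner-resolution independent.  A
nucleus's compartment is the majority layer label under its pixels, ties
broken by the layer under the area centroid (centroid-to-pixel mapping is
round-half-up so boundary centroids resolve deterministically).
Proximity features — nearest-neighbour distance and the count of other
nuclei within a 100 µm radius — are computed within one tile and
compartment, consistent with the layer-wise reporting of the shape
features.  ("Nuclei in 100 mpp" in the clinical literature this follows
is read as a 100 µm radius; the radius is configurable.)  Per tile and
compartment the pipeline reports the nucleus count NC, areal cellularity
φ = NC / compartment area (per µm²), and min/max/mean/median/sample-SD of
each morphometric.  The central-tendency aggregator is the median
(sources that describe the same analysis disagree between "median" and
"mode"; the mode is ill-defined for continuous features).

**PEL score.** The PEL count of a tile is the number of
inflammatory-class nuclei assigned to the connective-tissue compartment;
the PEL ratio divides by all nuclei in the tile.  No explicit distance
band defines "peri-epithelial": tiles are anchored on epithelium, so
their connective tissue is adjacent by construction.  Hotspots (coldspots)
are the k = 5 highest (lowest) scoring tiles of the slide heatmap, ties
broken by ascending tile index; slide-level features aggregate tile
features over the chosen tile set (hotspots by default) with the same
five aggregators.

**Association analyses.** Cohort summaries print percentages truncated
(not rounded) to one decimal — the convention under which the published
cohort table's values (e.g. 53/137 → 38.6) reproduce exactly.  The
feature screen regresses the binary transformation outcome on each
z-scored feature separately by OLS (the univariable slope t-test, n−2 df,
two-sided), with Benjamini–Hochberg step-up adjustment across the tested
family; zero-variance features are flagged untestable and excluded from
the family.  Whether the published screen was univariable or one joint
fit is ambiguous; univariable is the default and a joint fit remains
available through `statsmodels` on the same table.  PEL subgroup
comparisons (transformed vs not, within gender or age bins 0–50 / 51–70 /
71–100) use the two-sided Wilcoxon rank-sum test: exact enumeration when
the pooled sample is ≤ 20 without ties, otherwise the normal
approximation with midranks, tie correction and continuity correction.

**Survival analyses.** Kaplan–Meier, log-rank and Cox
proportional-hazards fits are delegated to `lifelines` with Efron tie
handling (tie handling is not published; Efron is the modern default, and
Efron = Breslow exactly in the untied case, which the tests exercise).
Continuous covariates are z-scored before fitting so hazard ratios are
per SD.  Risk dichotomisation uses the mean-hazard rule: per-subject
relative hazard exp(Xβ̂), cut at its mean, groups compared by log-rank;
the exponential form is fixed because the mean is not invariant under
monotone transforms of the linear predictor.  Harrell's C-index is
implemented in-package over pairs (i, j) with t_i < t_j and event_i = 1
(half credit for tied risks); confidence intervals are percentile
bootstrap over subjects with the model refitted per resample (B = 1,000
by default; the bootstrap aborts if > 5% of refits fail).  Per-feature
C-indices in the univariate table come from the univariable fit's linear
predictor.

**Evaluation harness.** Stratified five-fold cross-validation repeated
with three seeds; metrics are AUROC (trapezoidal, equal to the tie-aware
pairwise probability) and macro-F1, summarised by mean and SD over all
15 fold-results.  The slide classifier is a deliberately simple
L2-regularised logistic scorer on the aggregated features, with feature
scaling fitted inside each training fold; it exercises the protocol and
makes no claim of matching a trained weakly supervised CNN.

## Synthetic cohort generator

The generator emulates the *outputs* of the upstream segmentation
networks, not histology appearance (no colour or texture synthesis).

- **Geometry.** Horizontal layer bands (default height fractions
  keratin 0.10, epithelial 0.40, basal 0.15, connective 0.35) with a
  low-frequency sinusoidal boundary perturbation (amplitude ≤ 8% of the
  smaller adjacent band) so rete-like undulation and layer-boundary tie
  cases occur.
- **Nuclei.** Rasterised ellipses with class-dependent shape
  distributions (full major axis in µm, mean ± SD: epithelial 9.0 ± 1.2
  with axis ratio 0.70; lymphocyte 6.0 ± 0.6, ratio 0.90; fibroblast
  10.0 ± 1.5, ratio 0.45), placed by hard-core rejection on pixels —
  overlapping candidates are redrawn up to 30 times, shortfalls are
  reported, never silent.  Structural densities default to 3 / 45 / 65 /
  12 nuclei per 10⁴ µm² in keratin / epithelial / basal / connective;
  inflammatory nuclei are added in connective tissue at a slide-level
  intensity λ drawn uniformly from (2, 30) per 10⁴ µm².  Per-slide PEL
  abundance distributions are not published; these defaults were chosen
  once for statistical power and plausible area fractions, not
  biological calibration.
- **Outcomes.** Exponential proportional hazards: event time ~
  Exp(h₀·e^η) with η = β·z(PEL density, epithelial NC, basal NC),
  default β = (0.7, 0.3, 0.3), administratively censored at
  `censor_time`.  Defaults h₀ = 0.026/yr and censor_time = 15 yr were
  calibrated by simulation (including the default effect-size spread) so
  the marginal cohort shows ≈ 36% transformation and a mean observed
  transformation time ≈ 6.5 years, matching the published cohort's
  characteristics.  Grades are produced by rank-thresholding a noisy
  copy of η at the published marginal frequencies, so grading correlates
  with outcome as it does clinically.
- **Heatmaps.** Per-tile score = logistic(a·z(PEL count) + b·z(total
  NC) + ε), ε ~ N(0, noise_sd), defaults (1.5, 0.8, 0.25) — a surrogate
  for a trained classifier's probability map, monotonically coupled to
  composition.
- **Randomness.** A single seeded root `SeedSequence` spawns per-slide
  substreams, so cohorts are bit-reproducible and slides can be
  regenerated independently.
- **Raster-free twin.** `simulate_feature_cohort` draws the same count
  statistics directly (Poisson tile counts around layer-density
  expectations with a lognormal between-slide multiplier, CV 0.15) for
  power/calibration studies where rendering thousands of slides would be
  wasteful.  The raster route and the twin share the outcome and heatmap
  models.

**What passing tests do and do not show.** The generator provides ground
truth for geometry, counts and planted effects, so tests demonstrate
that the measurement and inference machinery is correct and calibrated
under the stated model (elliptical nuclei, banded layers, exponential
hazards, logistic heatmap coupling).  Real tissue violates all of these
in degree — irregular nuclear shapes, touching nuclei imperfectly split
upstream, non-proportional hazards, heatmaps driven by features other
than composition — so passing tests do not certify clinical performance;
they certify the arithmetic the pipeline would apply to real inputs.

## Study sizes and numerical choices

Simulation studies in the test suite and `scripts/acceptance.py` use:
50 replicate cohorts of n = 300 for Cox recovery (run at h₀ = 0.086/yr
so censoring is ≈ 30%, the regime the recovery claim is stated for);
2,000 null replicates (n = 80) for log-rank calibration; 500 replicates
of a 100-feature screen with 10 non-null features for FDR control; a
60-slide rendered cohort with strong noiseless coupling
(β = (1.2, 0.6, 0.6), heatmap coefficients (2.0, 1.0, 0.0)) for the
end-to-end cross-validation study; and 50 replicate 100-slide feature
cohorts for the univariate C-index ranking study.  These sizes were
chosen so each study's Monte-Carlo error is small relative to the
property being checked.

Degenerate inputs are defined, not crashed on: 1-pixel nuclei get
eccentricity 0 and axis lengths of one pixel; single-nucleus
compartments yield missing NND; compartments with zero area yield
missing φ with a warning; constant hazard scores make the mean-hazard
split degenerate and are flagged; non-converged or separation-prone Cox
fits return a flagged result rather than numbers.

Known limitations: no WSI pyramid reading (plain rasters only, assumed
already at the target mpp), no recurrence endpoint, no competing risks
or time-varying covariates, no proportional-hazards diagnostics beyond
the flagged-fit hook, and no attempt to reproduce numbers that require
the private clinical cohort and trained networks.
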