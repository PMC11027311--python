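# Methods

`gistrad` re-implements, end to end, an analysis linking computer-extracted
global radiomic features (GRFs) of screening mammograms to the strength of
radiologists' rapid "gist" impression — the 0–100 abnormality score an
expert reader produces after a half-second glance. The original analysis was
run on 4191 proprietary craniocaudal mammograms scored by 13 gist-expert
observers; those images and scores are not public, so this package pairs the
analysis chain with a synthetic-cohort generator that reproduces the
statistical structure the chain assumes. This note documents the model at
each stage, the tunable parameters and their defaults, what the synthetic
data does and does not emulate, and the numerical conventions.

## Analysis chain

1. **Preprocessing.** A binary breast mask is obtained by thresholding the
   grayscale image at gray level 100 (`>=` — the threshold value itself
   counts as breast). Right-breast images are mirrored about the vertical
   axis so the chest wall is on the left edge of every image. Image and mask
   are cropped to the tight per-image bounding box of the mask. (A
   dataset-wide common bounding box is available through
   `common_bounding_box` for the alternative reading of "maximum breast
   region size"; per-image cropping is the default because feature
   extraction only sees masked pixels either way.)

2. **ROI extraction.** The mask is eroded with a disk-shaped structuring
   element to remove the vendor-enhanced skin–air margin. The disk is the
   exact Euclidean one (offset (dr, dc) included iff dr² + dc² ≤ r²); a
   radius-r decomposed approximation used by some reference toolboxes can
   differ by a few boundary pixels. Out-of-bounds pixels count as
   background, so erosion also retreats from the image borders — including
   the chest-wall edge, where this removes an r-pixel strip. The clinical
   default radius is 100 px, tied to ~2800-row full-resolution mammograms;
   for smaller images the radius scales proportionally
   (`round(100 · rows / 2800)`).

3. **Feature extraction** (130 features per image, over ROI pixels only):
   - *110 GLCM features.* ROI intensities are quantized to N_g = 8
     equal-width bins of the ROI's own [min, max] (the max maps to bin N_g;
     a constant ROI maps to bin 1). For each pixel distance
     d ∈ {1, 3, 5, 9, 11} the four standard angles (0°, 45°, 90°, 135°) are
     accumulated into a single co-occurrence matrix; pairs are counted
     symmetrically by default and only when both pixels lie inside the ROI.
     22 statistics are read off each matrix: autocorrelation, contrast, two
     correlation variants, cluster prominence, cluster shade, dissimilarity,
     energy, entropy, two homogeneity variants, maximum probability, sum of
     squares variance, sum average, sum variance, sum entropy, difference
     variance, difference entropy, the two information measures of
     correlation, and the two normalized inverse-difference statistics.
   - *20 FOS features* on the raw (unquantized) ROI intensities: mean,
     standard deviation, skewness, kurtosis, minimum, the 5/10/15/20/25th
     percentiles, median, the 75/80/85/90/95th percentiles, maximum, and
     three ranges (max − min, P95 − P5, P99 − P1).

4. **Gist labeling.** The 13 observer scores per image are averaged; the
   top and bottom quartiles of the averaged scores over the *full pool*
   define the high- and low-gist classes, the middle half is excluded (kept
   and labeled, never dropped). Quartiles are rank-based — the ⌈n/4⌉
   highest/lowest images — which yields exactly 1048/1048 on a pool of 4191
   distinct scores; ties are broken by ascending image id, making the split
   deterministic. The split is computed once on the pool and the eight
   category datasets ("All" plus seven single categories) are subsets of
   it; per-category quartiles could not reproduce the unequal per-category
   class counts of the original design.

5. **Classification.** Per category dataset, an ensemble of 500
   bootstrap-aggregated decision trees separates high from low gist.
   Training folds are rebalanced by resampling minority-class rows with
   replacement until the classes are equal; the rebalancing happens *inside*
   each cross-validation training fold — duplicating before the split would
   leak copies of an image into its own test fold. Evaluation is stratified
   10-fold cross-validation (stratification guarantees both classes per fold
   under severe imbalance, e.g. 545 vs 71): each image is scored exactly
   once out-of-fold, the pooled out-of-fold scores give the rank-based
   (Mann–Whitney) AUC, and a stratified bootstrap (2000 replicates,
   percentile method) over the scored images gives its 95% CI. Feature
   importance is the forest's mean decrease in impurity, averaged across
   folds; permutation importance is available by flag.

6. **Scree selection.** A model's 130 importance scores are sorted
   descending (ties keep feature order) and the selection cut falls at the
   first occurrence of the largest consecutive gap. The rule is
   deterministic and parameter-free. Applied to the published importance
   table shipped with the package, it reproduces six of the eight published
   important-feature counts (All 7, Normal 7, Cancer 8, Prior-Visible 7,
   Prior-1 6, Prior-2 6); the published Missed (3) and Prior-Invisible (9)
   counts came from visual scree reading and no simple gap rule on the
   rounded printed scores recovers them (the gap rule yields 15 and 2) —
   these two models are reported but treated as a known divergence.
   Selected features are grouped into families by stripping the distance
   suffix from GLCM names and pooling the three range variants; the
   published flagged features group into exactly five families: cluster
   shade, standard deviation, skewness, kurtosis, range.

## Synthetic cohort

The generator emulates only what the analysis chain is sensitive to:

- **Geometry.** A half-ellipse breast (semi-axes 0.45·rows, 0.70·cols)
  touching the chest-wall edge (left for L, right for R) on a dark
  background (default gray level 40 + noise, clipped below 100), so
  thresholding at 100 exactly recovers the foreground.
- **Texture.** Foreground pixels are correlated Gaussian noise: a smoothed
  white-noise field (Gaussian kernel, σ = 2 px, renormalized to unit
  variance) carrying 60% of the variance, mixed with independent white
  noise. Each image has a hidden `latent_gist` score t·100 ∈ [0, 100] that
  drives three planted effect channels in proportion to t:
  - `cluster_shade_shift` (default 0.5): quadratic asymmetry
    z → z + a(z² − 1) of the *correlated* component, the channel GLCM
    cluster shade responds to;
  - `spread_shift` (default 3.0 gray levels): added to the baseline
    foreground standard deviation of 12 around mean 170;
  - `skew_shift` (default 0.2): the same quadratic asymmetry applied to the
    *white* component, driving first-order skewness.
  The channels are not fully independent — any asymmetry moves both
  skewness and cluster shade — so the defaults were calibrated to plant
  *comparable standardized shifts* (Cohen's d between latent-100 and
  latent-0 groups, ~6–11) on each channel's signature feature. Without that
  calibration a single strong channel (spread, whose d grows linearly and
  is mirrored by ~10 correlated percentile/range features) monopolizes the
  forest's impurity importance and the other planted families cannot
  surface. Foreground values are rounded and clipped to [100, 255]; the
  clipping bounds the asymmetry channel's achievable effect (d saturates
  near 6) and slightly distorts the planted moments, which is why planted
  effects are verified as group-mean *directions*, not exact magnitudes.
- **Categories.** Eight disjoint strata (Normal, Cancer, Prior-1, Prior-2,
  Prior-3, Missed, Prior-Visible, Prior-Invisible) drawn with weights
  proportional to the original cohort's type sizes. In the real taxonomy
  Missed/Prior-Visible/Prior-Invisible are retrospective regrades *of* the
  Prior-1 images; treating them as disjoint is a stand-in simplification
  that preserves what matters downstream (eight datasets with distinct
  class mixtures).
- **Latent gist.** A two-component mixture of truncated Gaussians (means
  25 and 75, sd 10, truncated to [0, 100]); the per-category weight of the
  high component defaults to the published per-category high-quartile
  fraction (e.g. 0.25 for Normal, 0.88 for Cancer), so planted texture
  differences align with category class imbalance the way the real data's
  did. The true distribution of averaged gist scores was never published;
  this mixture is a stand-in, not an estimate.
- **Observer panel.** Each of the 13 observers reports
  clip(latent + N(0, σ), 0, 100) with σ = 10 score units by default
  (gist scores have low inter-observer variability). Clipping, not
  resampling, models the bounded slider.

What the generator does **not** emulate: parenchymal anatomy, vendor
post-processing, pectoral muscle, breast-density structure, observer
expertise differences, and intra-observer correlation. Passing tests
therefore show that the *pipeline* recovers planted statistical structure
of the kind the original study reports — not that real mammograms carry
that structure, and the original real-data AUCs (0.69–0.84) and importance
magnitudes are deliberately out of reach.

## Numerical conventions and edge cases

- Entropies use the natural logarithm (configurable to base 2) with
  0·log 0 = 0.
- Both correlation variants are defined as 0 when a marginal is degenerate
  (σx·σy = 0); the first information measure of correlation is 0 when
  max(HX, HY) = 0; the second clamps 1 − e^(−2(HXY2−HXY)) at 0 before the
  square root.
- FOS standard deviation uses the n−1 denominator; skewness and kurtosis
  are the biased moment estimators (kurtosis non-excess, normal = 3,
  configurable to excess); both are defined as 0 for a constant ROI.
  Percentiles interpolate linearly between order statistics.
- Quantization of a constant ROI puts every pixel in bin 1; a single-pixel
  ROI yields an "empty GLCM" error naming the image and distance rather
  than NaNs.
- All randomness flows from explicit seeds: the cohort from
  `SyntheticParams.seed`, each pipeline stage from
  `SeedSequence([global_seed, stage_index])`, and cross-validation fold
  assignment, per-fold forests, oversampling draws, and the bootstrap CI
  from `ModelConfig.seed`. Identical configuration reproduces byte-identical
  artifacts.

## Problem sizes

The default demonstration cohort is 400 images of 128×128 px (erosion
radius 5 after scaling), which keeps a full pipeline run — cohort, 130
features per image, a cross-validated 500-tree model with bootstrap CI, and
a 10-repetition permutation null — in the low minutes on a single CPU while
leaving ~100 images per pooled class, enough for a stable 10-fold AUC. The
structural checks (quartile split, scree rule) run at the original study's
scale (4191 scores, the full 130×8 published importance table) because they
are cheap.

## Known limitations

- The exact formulas behind the original feature set's paired
  correlation/homogeneity variants are cited there, not printed; this
  package implements the canonical 22-statistic formulary and verifies it
  against independent brute-force summation, but row-by-row agreement with
  the original implementation cannot be established.
- The original quantization level count, symmetry setting, sum/difference
  statistic centering, and CI method are unreported; defaults (N_g = 8,
  symmetric counting, sum-average/difference-average centering, stratified
  bootstrap) are documented choices, each configurable where it is likely
  to matter.
- The scree rule is one formalization of a visual judgment; see the Missed /
  Prior-Invisible divergence above. Alternative elbow detectors are out of
  scope but `scree_select` is the single extension point.
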