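# Methods

## Problem and model

The package quantifies the difference in spatial texture between infrared
reflectance images of retinas with macular edema ("case") and healthy
retinas ("control"), and classifies images from that texture. Texture is
described at two orders:

- **First order**: the histogram of quantized gray levels and its central
  moments (mean, variance, skewness, kurtosis, energy = Σp², entropy =
  −Σp ln p). Kurtosis is non-excess; skewness and kurtosis are undefined
  (flagged, not imputed) when the in-mask histogram is degenerate.
- **Second order**: the gray-level co-occurrence matrix (GLCM) — the
  probability p(i, j) that a pixel of level *i* has a pixel of level *j*
  at a fixed offset — and scalar statistics of it (Haralick features plus
  the normalized inverse-difference variants IDN/IDMN, cluster moments,
  sum/difference marginal statistics, and the information measures of
  correlation IMC1/IMC2).

The pipeline is: preprocess → extract features → rank by one-way ANOVA F →
classify the top-k features → per-feature ROC/Youden diagnostics.

## Intensity model and GLCM conventions

- The image is quantized **once** to `ng` uniform bins spanning the
  in-mask intensity range; histogram and GLCM share this intensity model.
  Levels are indexed **1..Ng**, which fixes the scale of level-dependent
  features (autocorrelation, sum average, cluster moments). The in-mask
  maximum maps to level Ng; an all-equal region maps to level 1.
- `ng = 8` by default. Coarse quantization stabilises co-occurrence
  estimates on small images and is the regime in which typical reported
  histogram means (≈4–5) and sum averages (≈7) live. Configurable.
- Offsets: 0° → (0, d), 45° → (−d, d), 90° → (−d, 0), 135° → (−d, −d),
  with `d = 1` and a **symmetric** matrix (transposed pairs also counted)
  by default — Haralick's original definition. Pairs are counted only when
  both pixels are inside the analysis mask.
- Per-feature direction aggregation is the arithmetic mean over the four
  directions; the unaveraged per-direction block (4 × 20 values) is also
  emitted with `_0/_45/_90/_135` suffixes.
- All entropies use the natural logarithm with 0·ln 0 = 0; zero terms are
  skipped exactly, no epsilon offsets. HXY1 = −Σ p(i,j) ln(pₓ(i)p_y(j)),
  HXY2 = −Σ pₓ(i)p_y(j) ln(pₓ(i)p_y(j)).
- Cluster **shade** uses the cubic and cluster **prominence** the quartic
  exponent (the standard convention; sources occasionally swap the two).
- **Sum variance** is centred on the sum average by default
  (`sum_variance_center: sum_average`); Haralick's original centres it on
  the sum entropy, available as `sum_entropy`. Difference variance is
  centred on the mean of the |i−j| marginal.
- "Diffuse variance/entropy", a name that appears in parts of the
  literature, means difference variance/entropy (the p_{x−y} statistics).
- Undefined features (correlation when σₓσ_y = 0, IMC1 when
  max(HX, HY) = 0, histogram shape moments at zero variance) are flagged
  and excluded from ranking, never imputed.
- Histogram "energy" is Σp² of a normalized histogram and therefore lies
  in (0, 1]; published tables occasionally report values above 1 under an
  unstated scaling, which this package does not attempt to reproduce.

## Pre-processing

Median filter (3×3, reflection borders) then CLAHE (8×8 tiles, clip = 2×
the uniform bin height, mapped to the normalized clip limit of the
tile-wise equalization with 256 bins). The text this pipeline follows
describes filtering first and enhancement second; the stage order is
nevertheless configurable (`order`).

Optic-disc masking: contrast stretch (2–98 percentiles) → CLAHE →
morphological closing then opening with a disc structuring element
(radius 5 at 256×256; suppresses vessels) → threshold strictly above the
95th intensity percentile → largest bright 8-connected component →
dilation by 3 px. The threshold percentile is set slightly above the
expected disc area fraction (a radius-30 disc on a 256×256 frame covers
≈4.3% of pixels); a far higher percentile would clip the disc core only
and cannot reach useful overlap with the true disc. The complement of the
disc mask is the analysis mask used by **all** feature computation
(histogram and GLCM); `mask_optic_disc: false` disables masking, since
whether published analyses masked the disc is typically unstated. A flat
image yields an empty disc mask by policy (strict inequality at the
threshold).

## Feature selection and classification

- One-way ANOVA F per feature across the two groups (for two groups
  F = t² of the pooled-variance t-test, df (1, n−2)). Zero within-group
  variance with distinct means → F = +∞ (ranks above all finite F); zero
  between-group variance → F = 0, p = 1. Ties break lexicographically by
  feature name. Raw p-values are reported (no multiple-testing correction
  in ranking, mirroring the filter-selection protocol this reimplements).
- Selection is a filter on the full table before cross-validation by
  default (`nested: false`), reproducing the original protocol. With
  n ≈ 41 this is optimistically biased; `nested: true` re-ranks inside
  every leave-one-out training fold and is the statistically safer choice
  for new studies.
- Classifiers: linear SVM (C = 1), KNN (k = 3, Euclidean), Gaussian Naive
  Bayes (variance floor 1e−9). Features are z-scored with training-fold
  statistics inside every fit — unstandardized margins on mixed-scale
  texture features are pathological. KNN vote ties resolve alphabetically
  ("case" < "control"), i.e. toward the positive class.
- Protocols: leave-one-out (default; one-class training folds, which can
  only arise at the n = 3 minimum, predict the sole training class) and a
  stratified seeded 50/50 split (train size rounds up per class: 41
  samples → 21 train / 20 test). "Case" is the positive class everywhere.

## ROC and Youden diagnostics

Candidate thresholds are the midpoints between consecutive unique scores
plus ±∞, so reported cut-offs fall between classes rather than on a
sample. Both orientations are evaluated ("positive if ≤ t" and "positive
if > t"); the reported curve is the one with AUC ≥ 0.5. AUC is the
trapezoid over the swept (FPR, TPR) points, which equals the tie-corrected
Mann–Whitney statistic exactly (asserted in tests). The Youden cut-off
maximizes J = sensitivity + specificity − 1 over **both** orientations'
thresholds; ties prefer the reported orientation, then higher sensitivity,
then the lower threshold. All-identical scores give a degenerate ROC with
AUC 0.5 and J 0.

## Synthetic cohort generator

The generator emulates the study conditions this pipeline targets:
23 cases and 18 controls (41 images). Image size defaults to 256×256
(clinical IR-SLO scans are 768×768+; the smaller frame keeps a full run
in seconds without changing any qualitative behaviour and is
configurable).

- **Background**: a Gaussian random field — white noise smoothed with a
  Gaussian kernel of scale `corr_length`, min–max rescaled to the
  intensity range. The single smoothing scale maps monotonically onto
  GLCM correlation (verified: Spearman ρ > 0.9 across five scales), so
  `corr_length_control = 8` vs `corr_length_case = 2` reproduces the
  *direction* of the reported group difference (controls smoother, higher
  GLCM correlation). The magnitude of the synthetic contrast is chosen to
  be a strong, clearly separable effect, mirroring the reported perfect
  separability; it is not calibrated to any clinical effect size.
- **Optic disc**: blend toward `disc_brightness` with weight 1 inside
  0.85·radius and a cosine taper to 0 at the rim; centre jittered
  (SD 10 px) around the frame centre; clipped to the frame.
- **Vessels**: seeded random-walk tracks of width 3 px darkened by
  `vessel_contrast`, with a 1-px central streak brightened by half the
  contrast — the central light reflex characteristic of IR vessel
  appearance. Zero count or zero contrast is the identity.
- **Lesions** (cases only): 30 Gaussian blobs, radii 2–6 px, amplitude 40,
  at seeded positions recorded in the ground truth; they lower the GLCM
  correlation of an otherwise smooth field (verified by paired
  computation).
- Additive Gaussian pixel noise (SD 2) last; every compositing step clips
  to the declared bit-depth range.
- **Reproducibility**: each image uses an independent RNG substream keyed
  by (cohort seed, image index), so cohorts are bit-identical across runs
  and any single image can be regenerated in isolation.
- **Null cohort** switch: identical parameters in both groups (control
  background, no lesions) for type-I-error testing.

What the generator does **not** emulate: optical properties of IR-SLO
scanning, photorealistic fundus anatomy (macula, choroid), hyperreflective
artefacts, and between-eye correlation of subjects contributing two eyes
(images are generated independently; clinical cohorts of 41 images from
21 subjects are not). Passing tests on this cohort therefore demonstrate
that the pipeline's machinery is correct and recovers a known injected
texture effect — not that the clinical effect size or the perfect clinical
classification would replicate on real IR images.

## Problem sizes used in tests

The acceptance checks run the full default cohort (41 images at 256×256,
~15 s). Error-control checks use one 20+20 null cohort at 128×128 with
100 seeded balanced relabelings for the Bonferroni minimum-p check and 50
label permutations for the LOOCV chance-level check — each relabeling of a
null cohort is a draw from the null, which makes the check affordable at
desk scale. Oracle-equivalence checks (GLCM vs brute-force enumeration,
Haralick vs literal formulas, AUC vs Mann–Whitney, Youden vs exhaustive
search) run on hundreds to a thousand small random instances.

## Known limitations

- The 100%/AUC = 1.0 outcomes are properties of the strongly separated
  synthetic twin; they mirror reported headline numbers but carry no
  clinical evidence.
- On a strongly separated cohort several features saturate at AUC = 1.0;
  the AUC ranking breaks such ties lexicographically, so "the" top feature
  is only unique up to that tie set (the GLCM correlation is always in it).
- Non-nested selection before LOOCV is reproduced as the default protocol
  despite its optimism; see above.
- The percentile-threshold disc segmentation assumes the disc is the
  largest bright compact structure and covers less than
  (100 − od_threshold_percentile)% of the frame; very large or very dim
  discs need the percentile adjusted.
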