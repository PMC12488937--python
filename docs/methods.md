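# Methods

## The measurement model

An organoid in a brightfield image is treated as a single dark connected
region on a light background. Segmentation is global Otsu thresholding on
the 8-bit image with an optional additive threshold offset (the stand-in
for interactive manual adjustment), retention of the largest 8-connected
component, and hole filling. Fluid-filled cysts appear *bright* inside the
dark body; they become holes at the global threshold and are therefore
filled into the organoid mask and measured separately (cyst area is
expressed as a proportion of the entire organoid area).

Shape parameters, all derived from the filled mask with pixel size
`pixel_size_um` (µm/px):

| parameter | definition |
|---|---|
| area | foreground pixel count × px² |
| perimeter | Crofton estimate, 4 directions |
| Feret diameter | max pairwise distance over boundary-pixel corners, rotating calipers |
| aspect ratio | major/minor axis of the moment-matched ellipse |
| circularity | 4π·area/perimeter², capped at 1 |
| roundness | 4·area/(π·major²), capped at 1 |
| solidity | area / convex-hull area |

Numerical choices worth stating:

* **Feret over pixel corners, not centers.** The isodiametric inequality
  area ≤ π·Feret²/4 must hold for any planar set; a digitized disc
  violates it under a pixel-center measurement (pixel-count area slightly
  exceeds π·(center Feret)²/4). Measuring the diameter of the union of
  pixel *squares* — i.e. over the 4 corners of each boundary pixel —
  restores the inequality exactly and better matches the physical extent
  of the object. The rotating-calipers implementation is exact: it is
  property-tested against an O(n²) brute-force pairwise maximum, with
  extra antipodal candidate pairs to cover exactly-parallel hull edges,
  which are common on the pixel lattice.
* **Crofton perimeter.** A polygon through boundary pixels overestimates
  smooth outlines by the staircase effect (~5% on a disc, pushing disc
  circularity to 0.90); the 4-direction Crofton formula is accurate to
  ~0.2% on discs, so a discretized disc measures circularity ≈ 1 (capped).
* **Cyst detection.** Interior pixels brighter than an interior-specific
  Otsu threshold form candidates; regions smaller than
  `min_cyst_area_um2` (default 5000 µm², about a 40 µm-radius cavity) are
  discarded, and if the Otsu classes are separated by fewer than 30 gray
  levels the interior is declared unimodal and cyst-free rather than
  split on noise. Real cyst identification involves judgment calls this
  detector does not model; its parameters are exposed.
* Fluorescence: CFI = integrated density − area × background-mean
  (background region is an explicit input, since conventions differ
  between labs), plus the size-normalized CFI/area variant; MFI is the
  mean intensity over the mask; section Feret reuses the mask Feret.

## Statistical pipeline

* **Screen.** Point-biserial r (Pearson with a High=1/Low=0 encoding);
  two-sided p from the exact t reference distribution (t transform with
  n−2 df); BH step-up FDR within the nine-feature family; selection rule
  p_adj < 1e−5 AND |r| > 0.5. Negative r means "larger in low-quality
  organoids", the direction expected for size and cyst burden.
* **Clustering.** z-scores use the sample SD (ddof = 1). The elbow is made
  deterministic: k* = argmax over k ∈ [2, k_max−1] of the WSS second
  difference wss(k−1) − 2wss(k) + wss(k+1). k-means is Lloyd's algorithm
  with random-point initialization, best of 20 starts under one seed
  (default 111). Cluster→label mapping assigns High to the cluster with
  the larger expert-High proportion; exact ties go to the smaller-mean-
  Feret cluster. PPV/NPV/Se/Sp treat High as the positive class; an empty
  margin yields a missing rate with a warning rather than a crash.
* **Cutpoint.** Candidate thresholds are midpoints between consecutive
  sorted unique values plus ±∞ sentinels — so a reported cutoff falls
  between observations, the convention of standard cutpoint software.
  Orientation is chosen per feature so AUC ≥ 0.5. J ties break toward
  higher specificity, then the smaller threshold. Classification
  convention for "high feature ⇒ Low" features (Feret): value < threshold
  → High; values exactly at the threshold are Low. This boundary
  convention is configurable via the direction argument.
* **Deconvolution.** Per-sample CPM normalization followed by NNLS on the
  raw signature columns and renormalization of the coefficients to the
  simplex. This is a deliberately simple estimator: it is deterministic,
  scale-invariant per sample, exact on noiseless mixtures, and accurate
  for well-conditioned signatures (mean absolute mesenchymal-fraction
  error < 0.05 at 10% multiplicative noise, 2000 genes, 10 cell types).
  It does not model count overdispersion, per-cell-type expression
  heterogeneity or reference mismatch the way Bayesian deconvolution
  methods do; with a poorly conditioned or mismatched signature its
  errors will be larger and less honest about uncertainty.
* **Group tests.** Wilcoxon rank-sum, two-sided; exact null when both
  groups have ≤ 25 samples and the data are tie-free, otherwise the
  normal approximation with tie correction. CV = SD/mean × 100 with
  sample SD; a zero-mean line reports a missing CV. The MC–Feret
  association is summarized by Spearman's rho (average ranks for ties, t
  transform p); a Pearson variant is exposed for users who prefer the
  linear statistic.

## The synthetic cohort

The generator emulates a 12-line × 6-organoid day-30 cohort with two
latent quality classes and is the package's ground-truth test bed.

* Per-line probability of a High-quality organoid: mean ≈ 0.72 with
  strong line-to-line spread (0.3–0.95), reflecting that quality is
  largely a property of the hPSC line and giving ≈ 54 High / 18 Low per
  cohort.
* Feret: lognormal, median 2400 µm (High) / 3800 µm (Low), log-SD 0.15 —
  about 3 SD of separation, so a mid-3000s µm boundary separates the
  classes well but not perfectly.
* Cyst count: Poisson, mean 0.2 (High) / 3.0 (Low); cyst-area ratio ~
  Beta-based, zero when no cysts.
* Shape descriptors (circularity, roundness, solidity, aspect ratio) are
  deliberately *weakly* class-separated (|r_pb| ≈ 0.3): day-30 experts
  key on size, cysts and outline, and the screen should reject the weak
  descriptors at the |r| > 0.5 stringency.
* MC fraction = inverse-logit(−7.29 + 1.81·10⁻³·Feret + ε), ε ~
  N(0, 1.6) on the logit scale. The link keeps fractions in (0,1); the
  slope/noise pair puts most fractions in the few-percent-to-~70% range
  and yields a Spearman(MC, Feret) around 0.6. The remaining mass is
  split over nine other neural/non-neural cell types by a symmetric
  Dirichlet.
* Expression: a synthetic genes × cell-types signature (lognormal
  baseline, a dedicated 5% marker block per type, so the mixture is well
  conditioned), bulk = signature · fractions × i.i.d. unit-mean lognormal
  noise with CV 0.1.
* Fluorescence: MFI(channel) = baseline + slope · MC + Gaussian noise,
  positive slopes for CD73/CD105 (mesenchymal markers), negative for
  MAP2; the section Feret is a noisy 0.55–0.95× view of the whole-mount
  Feret (cryosections rarely pass through the widest plane).
* Rendering: the outline is an ellipse (major axis = Feret) in polar
  coordinates, with small Gaussian bumps (buds) for High and low-order
  random harmonics (irregularity) for Low quality; the polygon is
  rescaled iteratively so the *rasterized* mask's Feret matches the true
  Feret within ~1 px. Cysts are bright non-overlapping interior discs
  with stored ground-truth masks. Body/cyst/background gray levels are
  90/185/220 with σ = 3 noise — enough contrast structure for Otsu and
  the cyst detector, with no pretense of photorealistic texture.
* Determinism: one integer seed drives everything; per-organoid render
  and expression streams are spawned from it, so identical configurations
  produce byte-identical cohorts including images.

What passing tests on this cohort do **not** show: robustness to uneven
illumination, debris, touching organoids or out-of-focus images; expert
disagreement (the synthetic "expert" label *is* the ground truth class);
reference-atlas mismatch in deconvolution. The image round trip
guarantees the geometry pipeline, not the segmentation of difficult real
micrographs.

## Problem sizes

Default test and reproduction runs use the 72-organoid cohort, 2000-gene
/ 10-cell-type signatures, and 100–120 randomized instances for exact
property checks (Feret vs brute force, Youden vs exhaustive scan) —
small enough to run in seconds, large enough that the property checks
cover degenerate geometry (collinear hulls, tied feature values, parallel
hull edges).

## Known limitations

* The 10⁻⁵/0.5 screen stringency and the seed-111/20-start clustering
  protocol are defaults mirroring the intended application, not tuned
  values; change them through the configuration.
* The cutpoint is reported without a confidence interval; bootstrap CIs
  are out of scope.
* Published per-organoid statistics (Youden J 0.68 at 3050 µm, etc.) can
  only be recomputed with the study's controlled-access source-data
  table; the corresponding acceptance test fails until that table is
  supplied at `data/source_data_organoids.csv`.
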