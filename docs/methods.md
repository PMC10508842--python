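# Methods

## Problem and pipeline

Men with low-risk prostate cancer on active surveillance (AS) are monitored
with serial PSA measurements, MRI and repeat biopsies. The question this
package addresses is whether *changes* in quantitative image texture between
a baseline and a follow-up bi-parametric MRI (T2-weighted + ADC), combined
with changes in routine clinical variables, are associated with pathologic
upgrade at repeat biopsy (AS+ vs AS−).

The pipeline has four stages:

1. **Synthetic cohort generation** — serial pseudo-MRI volumes with a known
   progression signal (no patient data are bundled or downloaded).
2. **Preprocessing** — landmark-based intensity standardization of T2W
   volumes; ADC maps are quantitative and are never standardized.
3. **Radiomic feature extraction** — a 252-entry feature vector per lesion
   and sequence at each timepoint; delta features are follow-up − baseline.
4. **Feature selection and classification** — correlation pruning, mRMR,
   random forests for five model variants inside 100 runs of threefold
   cross-validation, with rank-AUC and operating-point metrics.

## Synthetic cohort model

Each patient contributes two timepoints × two sequences on a common grid
(default 48×48×16 voxels at 1×1×3 mm) plus a spherical lesion mask
(radius 6 mm, in-plane center jittered ±2 voxels per patient). Intensities
are built from three parts:

* a background Gaussian random field (correlation length 4 mm, sd 6) around
  a tissue mean of 120;
* a lesion texture field: zero-mean Gaussian random field inside the mask
  with correlation length 2 mm and sd 12 (T2W units), plus a −20 lesion
  offset (lesions are dark on T2W);
* i.i.d. voxel noise (sd 3).

Random fields are produced by Gaussian-smoothing white noise (kernel sigma =
correlation length), demeaning, and rescaling to the target sd; the marginal
sd is therefore exact by construction. The ADC companion is a
contrast-inverted copy of the lesion texture (slope −4 per T2W unit) with a
−350 lesion offset around a 1400 background and independent noise (sd 40),
so the two sequences carry correlated but non-identical signal and the
lesion stays dark on ADC.

**Progression signal.** AS+ lesions change texture at follow-up: correlation
length and amplitude are multiplied by configurable effects (default 1.3
each), and the mask radius grows by a factor 1.15. AS− follow-up lesions are
fresh draws from the baseline texture distribution with unchanged geometry.
Per-scan texture parameters carry log-normal biological jitter (sd 0.15 on
amplitude, 0.10 on correlation length); without it every AS+ patient would
show an identical, trivially separable shift. The 30 % texture change was
fixed once as a plausible progression magnitude that leaves the delta model
mid-range rather than saturated, so that adding clinical information can
still help. Follow-up T2W scans get a patient-level multiplicative intensity
drift (log-sd 0.08), which is what the standardization stage corrects.

**Clinical table.** Baseline PSA is log-normal with mean 5.5 and sd
2 ng/ml; PSA and tumor-volume deltas are normal with a standardized
between-arm difference d = 0.8 (defaults). The clinical tumor volume is the
mask-derived volume plus measurement noise at baseline, with its own normal
delta; it is deliberately not recomputed from the grown follow-up mask — the
volume-effect knob stays meaningful and the discrepancy mimics
planimetric-vs-ellipsoid measurement differences. PIRADS (3–5) is drawn with
arm- and timepoint-dependent probabilities. Defaults are loosely matched to
the demographic ranges typical of AS cohorts and are not calibrated
estimates.

Two named conditions derive from a config: `null_effects` zeroes every
between-arm difference (calibration experiments), and
`delta_texture_condition` freezes lesion geometry so the imaging signal is
carried purely by the follow-up texture change (signal-recovery
experiments). Cohort generation is a pure function of the config, including
its seed.

**What the generator does not emulate:** MRI physics, bias fields, anatomy,
registration error, reader variability in delineation, and biopsy sampling
error. Passing tests therefore demonstrate that the pipeline recovers a
known signal of this kind at n = 30 — not clinical performance on real
scans.

## Intensity standardization

T2W scans lack tissue-specific intensity meaning across visits. Each
volume's histogram landmarks — deciles 10–90 anchored by the robust 1st and
99th percentiles, computed over the nonzero "body" region by default — are
mapped by a monotone piecewise-linear function onto template landmarks
averaged over the cohort's baseline T2W scans. Values beyond the outer
anchors continue the outer segments linearly (clipping would create plateau
artifacts inside texture windows). The map is idempotent on landmarks up to
percentile-interpolation round-off. Mask transfer between grids uses
nearest-neighbor (center-containment) resampling; registration itself is out
of scope and synthetic volumes are generated pre-aligned.

## Feature vector (252 per sequence)

All texture operators act on 2D axial slices; the ROI gates which voxels are
evaluated but windows keep their full neighbourhood (clipped only at image
borders). The 252 entries decompose as:

* **First-order (72):** 18 statistics of the ROI intensities of each slice
  (mean, median, sd, range, min, max, p10/p25/p75/p90, IQR, skewness,
  excess kurtosis, energy Σv², RMS, mean absolute deviation, 32-bin
  histogram entropy, uniformity), each summarized across slices by four
  moments (mean, population variance, skewness, kurtosis).
* **Windowed texture maps (180):** 45 per-voxel descriptor maps — 13
  gray-level co-occurrence (Haralick) statistics at window sizes 3, 5 and 7;
  5 Gabor orientation magnitudes; 1 CoLlAGe map — pooled over all lesion
  voxels of all slices and summarized by the same four moments.

Names follow `<moment>_<family>_<descriptor>[_w<window>]`, e.g.
`kurtosis_haralick_sum_entropy_w5`.

**GLCM details.** Intensities are quantized to 16 equal-width levels over
the slice-ROI range (fixed per slice so neighbouring windows are
comparable); the co-occurrence matrix pools the four 2D offsets
(0,1),(1,0),(1,1),(1,−1) with symmetric counting. The 13 statistics are
entropy, energy, inertia, inverse difference moment, correlation,
information measure of correlation 1, sum average/variance/entropy,
difference average/variance/entropy, and contrast. Inertia and contrast
share the classical formula; both are emitted and the 0.90 correlation
pruning removes one downstream. Entropies are in bits; the correlation of a
constant-marginal matrix is defined as 0.

**Gabor bank.** Five zero-DC (mean-subtracted) cosine-carrier kernels at
orientations 0°, 36°, 72°, 108°, 144°, single wavelength 4 voxels, sigma =
wavelength/2. The map value is the response magnitude. Zero-DC makes the
maps invariant to constant intensity shifts.

**CoLlAGe.** Per voxel: Sobel gradients; the dominant local orientation is
the principal direction of the 5×5 window's gradient scatter matrix
(angle = ½·atan2(2Sxy, Sxx−Syy), taken mod π); orientations are binned into
8 bins over [0, π); the feature is the Shannon entropy of the binned
orientations within the window. All-zero-gradient windows are defined to
have entropy 0.

**Degenerate-case conventions.** Skewness/kurtosis of fewer than 3 values or
zero variance are 0; a constant quantization range maps everything to level
0; a single-slice lesion has zero across-slice variance/skewness/kurtosis by
these rules. Every vector is checked to be finite and exactly 252 long.

## Selection and classification

* **Pruning:** greedy scan in canonical feature order; a feature is dropped
  iff |Pearson r| ≥ 0.90 against any already-retained feature; constant
  features drop first.
* **mRMR (MID criterion):** features are discretized to 3 states at
  mean ± sd (training-fold statistics); the first pick maximizes I(f; y),
  subsequent picks maximize I(f; y) − mean I(f; s) over the selected set s.
  Ties break toward canonical order. The number of selected features
  defaults to 5 (configurable); selection frequency across folds and runs is
  reported.
* **Classifier:** random forest (500 trees by default, √p features per
  split, bootstrap), fixed-seeded. Integrated variants stack a second-stage
  forest on the first stage's out-of-bag risk score plus the clinical
  covariates (PSA and tumor volume — the two used by the integrated models),
  trained within the fold; this mirrors integrating clinical parameters with
  classifier risk scores rather than refitting jointly (the joint refit is
  available via the optimistic-protocol switch's machinery but stacking is
  the default reading).
* **Cross-validation:** 100 runs of stratified threefold CV; run r seeds the
  fold shuffle and forests with base_seed + r. Pruning, discretization
  statistics, mRMR and forest fitting happen inside training folds only
  (a leakage test asserts training artifacts are bit-identical under
  test-label permutation). A `select_within_folds=False` switch reproduces
  the optimistic whole-cohort-selection protocol. Each run pools its
  test-fold scores into one AUC; reports carry mean ± sd across runs.
* **Metrics:** rank-based (Mann-Whitney) AUC with ties counting ½;
  confusion-matrix rates at the Youden-J-maximizing threshold (ties resolve
  to the lower threshold); specificity/PPV/NPV at the largest threshold
  reaching 90 % sensitivity. Empty confusion-matrix denominators yield 0.
  Clinical comparators (PSA, tumor volume, PIRADS, and their deltas) are
  scored by univariate rank AUC.
* **Rank-sum screening:** the two-sided Wilcoxon rank-sum test uses the
  exact null distribution when n₁+n₂ ≤ 12 without ties, otherwise the normal
  approximation with tie and continuity corrections; it annotates the most
  frequently selected features in the report.

## Numerical and design choices

* Windowed Haralick maps are computed by sharing one sliding-window pass per
  slice and batching the statistic formulas over all ROI windows; an
  exhaustive per-window brute-force oracle pins every value in the tests.
* The 252-entry decomposition (18×4 + 45×4) is fixed in code; the
  bi-parametric concatenation used by the models is 504 entries with
  `t2w__`/`adc__` prefixes.
* The context margin kept around a lesion crop (8 voxels) covers the largest
  kernel reach (Gabor half-width 6), so cropping never changes any map value
  away from true image borders.
* All randomness flows from explicit integer seeds; cohorts, feature tables
  and evaluation reports are byte-reproducible under a fixed config.

## Problem sizes used in the shipped experiments

Property suites run the full pipeline at the cohort's native n = 30 but with
forests of 100–150 trees and, for the replicate-cohort ordering experiment,
25 CV runs per cohort over 20 cohorts; AUC means plateau well below these
forest sizes, which were chosen to keep the experiments comfortably
repeatable on one CPU. The acceptance script uses 100 runs and 150-tree
forests per variant.

## Known limitations

* The null-calibration property (every variant's mean CV AUC within
  [0.40, 0.60] on a zero-effect cohort) concerns a *single* simulated cohort:
  the arms are exchangeable so the expected AUC is exactly 0.5, but one
  n = 30 cohort's intrinsic repeated-CV AUC has a cohort-to-cohort sd of
  roughly 0.09 (measured over replicate null cohorts), so individual null
  cohorts can land outside the band by chance.
* The replicate-cohort ordering experiment compares per-cohort mean AUCs by
  sign test. At the default 30 % texture effect the paired delta-vs-baseline
  gap (~+0.1) is similar in size to the between-cohort spread of the
  baseline model's chance AUC, so the pairwise sign test at 20 cohorts has
  modest power for that comparison even though the across-cohort average
  AUCs order clearly; the integrated-vs-delta comparison is consistently
  positive.
* Under the full default conditions the deterministic lesion growth factor
  makes size-sensitive delta features (e.g. per-slice energy) extremely
  separable, so the delta models approach AUC 1 — the delta-texture-only
  condition is the informative benchmark for texture recovery.
* Texture operators are 2D and slice-wise; anisotropic voxel spacing enters
  only the lesion geometry, not the kernels (the Gabor wavelength is in
  voxels).
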