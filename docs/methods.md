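# Methods

## The measurement problem

On axial T2-weighted MR slices of the lumbar spine, fat is bright and lean
muscle is dark, so the composition of a paraspinal muscle (multifidus,
erector spinae) can be quantified by tracing the muscle outline and
splitting the pixels inside it into fat and muscle by an intensity
threshold.  The quantities of interest are the total cross-sectional area
(CSA), the functional CSA (lean muscle), the fat CSA — all in cm² — and the
fat fraction (fat pixels / ROI pixels, a 0–1 proportion).  Manual threshold
selection is reliable but slow and rater-dependent; `musclefat` implements
a fully automated threshold chain and the agreement statistics used to
validate such a chain against a reference method.

## Pipeline

Given a grayscale slice, a traced polygon ROI and the pixel geometry:

1. **CLAHE.** The image is divided into `tile_rows x tile_cols` rectangles
   (default 8x8). Each tile's 256-bin histogram is clipped at
   `clip_limit` x the uniform bin height (default 2.0; the clipped excess is
   redistributed uniformly over all bins) and converted into an equalization
   lookup table: the clipped CDF rescaled onto `[0, L-1]`. Each output pixel
   blends the lookup tables of its up-to-four nearest tile centers
   bilinearly; pixels beyond the outermost centers clamp to the edge tile.
   Local equalization flattens slow multiplicative intensity bias (MR field
   inhomogeneity) so a single threshold is meaningful across the ROI; the
   blending avoids visible tile seams.
2. **Contrast stretch.** The window between the 1% and 99% intensity
   quantiles (1% saturated per tail, configurable) is mapped linearly onto
   the full range; quantiles use linear interpolation between order
   statistics. A constant image is passed through with a warning rather than
   rejected, so pathological ROIs degrade gracefully.
3. **ROI rasterization.** Pixel coordinates are `(x, y) = (column, row)`,
   0-based, pixel centers at integers. A pixel belongs to the ROI iff its
   center is inside the polygon under the even–odd rule; centers exactly on
   an edge are resolved by the half-open upward-ray convention (lower/left
   edges belong to the polygon). Self-intersecting outlines are rejected.
4. **Otsu threshold.** ROI intensities are normalized to `[0, 1]` and
   binned into 256 equal-width bins; every interior bin boundary is scanned
   and the one maximizing the between-class variance
   `w0*w1*(mu0-mu1)^2` is selected (smallest boundary on ties; the returned
   threshold is the upper edge of the lower class). The threshold is
   computed from ROI pixels only, making it muscle- and slice-specific; an
   alternative using the cropped bounding rectangle would mix in background
   and is deliberately not the default. A constant ROI is degenerate: zero
   between-class variance, flagged, no fat called.
5. **Classification and areas.** Fat = ROI pixels with normalized intensity
   strictly greater than the threshold (the conservative choice at the
   degenerate boundary), muscle = the complement, so fat + muscle = ROI
   exactly. Areas are `count x pixel_area_mm2 / 100` cm²; CSA is *defined*
   as FCSA + fat CSA so conservation is a structural identity, not a
   numerical coincidence. The fat fraction is a count ratio and therefore
   independent of pixel geometry.

Pixel geometry is a required user input (direct spacings, or acquisition
matrix + field of view; direct spacings win when both are given): the image
files themselves carry no physical scale.

## Agreement statistics

* **ICC(2,1)** — two-way random-effects, absolute agreement, single
  measure: `(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))` from the
  two-way ANOVA mean squares. The 95% CI uses the F-based procedure of
  McGraw & Wong (1996) with Satterthwaite denominator degrees of freedom —
  the method behind the common statistics packages, as the original
  analysis software does not document an alternative. Negative estimates
  are reported as computed but categorized "poor".
* **SEM** = `S * sqrt(1 - r_xx)` with `S` the between-subject SD and `r_xx`
  the reliability coefficient; same units as the measurement.
* **Bland–Altman**: bias = mean difference, limits of agreement =
  bias ± 1.96 x SD (sample SD, n-1; the literal 1.96 of the classic
  formulation, not a t quantile). Normality of the differences is
  summarized descriptively (skewness, excess kurtosis) rather than gated on
  a formal test.
* **Interpretation bands** (Portney–Watkins): < 0.50 poor, 0.50–0.74
  moderate, ≥ 0.75 excellent; boundaries belong to the upper band.
* `agreement_report` matches two measurement tables on subject keys,
  excludes unmatched rows with a warning, and emits mean, SD, ICC with CI,
  SEM and the Bland–Altman summary per parameter and group.

## Synthetic phantoms

`generate_phantom` builds a slice the pipeline can be scored against: an
elliptical muscle region (traced as a 64-gon, whose own raster is the truth
ROI so pipeline and truth see the identical pixel set), fat deposited as
random disks (radius 2–6 px by default) until the realized fat fraction is
within ±0.02 of the target, a smooth multiplicative bias field (three
low-frequency cosine modes with random orientation and phase, rescaled to
1 ± amplitude — the standard smooth-field model of MR inhomogeneity),
additive Gaussian noise, clipping to [0, 1] and quantization to the bit
depth.  Defaults: 256x256 image, muscle 0.25 / fat 0.75 on the normalized
scale, noise SD 0.05, bias amplitude 0.2, target fat fraction 0.55 (the
degree of fatty infiltration typical of symptomatic paraspinal muscle).
`generate_cohort` perturbs the target fat fraction (SD 0.10) and ellipse
axes (SD 3 px) per subject, emulating a ~30-patient sample; with zero
between-subject SD the subjects are exact replicates.

What the phantom does **not** emulate: anatomy (muscle boundaries against
neighboring bright structures), Rician noise statistics, partial-volume
mixing at fat/muscle interfaces, and through-plane effects. Passing the
recovery tests therefore demonstrates the correctness of the thresholding
chain under the stated intensity model, not clinical accuracy.

## Numerical choices

* Tile grids that do not divide the image use rounded equal partitions; the
  last tile absorbs the remainder.
* Histograms bin intensity `v` into `min(floor(v * n_bins / L), n_bins-1)`.
* Otsu ties break toward the smallest threshold; fat classification is
  strict (`>`), so a degenerate threshold yields zero fat.
* ICC values within 1e-12 of 1 are snapped to 1 (identical-column float
  residue); a zero-variance matrix returns ICC 1 with a degenerate flag.
* All phantom randomness flows from one integer seed through a local
  `numpy.random.Generator`.

## Known limitations

* **Otsu assumes a two-class histogram.** On a one-class (all-muscle) ROI
  with noise, the scan bisects the noise distribution and reports a
  spurious fat fraction near 0.5. Only the exactly-constant ROI is detected
  as degenerate. This is inherent to global Otsu thresholding; a
  bimodality guard would introduce a sensitivity parameter the method does
  not define.
* **Preprocessing is close to neutral on well-separated classes.** A
  multiplicative bias field scales fat and muscle intensities equally, so
  with a 3:1 class ratio and amplitude ≤ 0.2 the class ranges never
  overlap and the unpreprocessed within-ROI threshold is already
  near-exact on phantoms (recovery error ~1e-4). In that regime CLAHE's
  local equalization adds a small error of its own (~0.004 fat-fraction
  units, still well within tolerance) rather than helping; its value lies
  in lower-contrast, more strongly corrupted data than the phantom's
  default regime.
* Single-slice areas only; volumes are out of scope, as is automatic ROI
  segmentation.
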