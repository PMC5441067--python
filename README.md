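# musclefat

Automated thresholding of paraspinal muscle composition on axial
T2-weighted MRI, with the measurement-agreement statistics used to validate
it and a synthetic phantom generator to test every stage without clinical
data.

## What it does

On T2-weighted images fat is bright and lean muscle dark. Given a single
slice, a manually traced muscle outline (polygon vertices in pixel
coordinates) and the pixel geometry, `musclefat` computes four
composition parameters for the traced muscle:

* **CSA** — total cross-sectional area of the ROI (cm²),
* **FCSA** — functional (lean muscle) CSA,
* **fat CSA** — area classified as fat,
* **fat fraction** — fat pixels / ROI pixels (0–1).

The threshold separating fat from muscle is selected automatically: the
slice is contrast-enhanced by contrast-limited adaptive histogram
equalization (CLAHE) followed by a 1%-per-tail saturating contrast
stretch, the ROI is rasterized by a pixel-center even–odd rule, and Otsu's
method — the split of the normalized ROI histogram maximizing the
between-class variance σ²_B(t) = ω₀ω₁(μ₀ − μ₁)² — picks the threshold.
Pixels above it are fat; `CSA = FCSA + fat CSA` holds exactly.

For method validation the package implements ICC(2,1) (two-way
random-effects, absolute agreement, with McGraw–Wong 95% CI), the standard
error of measurement `SEM = S√(1 − r_xx)`, Bland–Altman bias and 95% limits
of agreement (bias ± 1.96·SD of the differences), and the Portney–Watkins
ICC interpretation bands. `agreement_report` turns two measurement tables
into a per-parameter reliability report with Bland–Altman plots.

Because no clinical images ship with the package, a phantom module
generates elliptical "muscle" slices with disk-shaped fat deposits at a
known fat fraction, a smooth multiplicative bias field (MR inhomogeneity)
and Gaussian noise — ground truth included — so recovery error can be
measured exactly. See `docs/methods.md` for the full model description.

## Worked example

Generate one phantom and quantify it with the automated pipeline
(pixel spacing 1 mm × 1 mm):

```sh
$ musclefat phantom --n 1 --seed 7 --out demo
INFO wrote 1 phantom case(s) to demo
$ musclefat quantify --image demo/S001.png --roi demo/S001_roi.csv \
    --spacing-mm 1 1 --out demo/measurements.csv
INFO S001.png: csa=23.940 cm^2 fat_fraction=0.536 thr=0.766
$ cat demo/measurements.csv
subject_id,slice_id,muscle,side,level,csa_cm2,fcsa_cm2,fat_csa_cm2,fat_fraction,threshold
S001,1,unspecified,unspecified,unspecified,23.94,11.12,12.82,0.535505,0.765625
$ cat demo/truth.csv
subject_id,true_fat_fraction,roi_count,fat_count
S001,0.531328,2394,1272
```

The traced ellipse covers 2394 pixels = 23.94 cm² at 1 mm pixels; the
pipeline's threshold (0.766 on the normalized intensity scale, chosen by
Otsu within the ROI after contrast enhancement) calls 53.55% of the ROI
fat, against a ground-truth fat fraction of 53.13% — a recovery error of
0.004. The same API is available from Python:

```python
from musclefat import PhantomSpec, PixelGeometry, generate_phantom, quantify_slice

img, roi, truth = generate_phantom(PhantomSpec(seed=7))
m = quantify_slice(img, roi, PixelGeometry(1.0, 1.0))
print(m.fat_fraction, truth.true_fat_fraction)
```

For clinical images, pass the acquisition geometry either as spacings
(`--spacing-mm`) or as matrix size plus field of view
(`--matrix 256 256 --fov-mm 256 256`); the command refuses to run without
it, since image files carry no physical scale.

Two measurement tables (e.g. automated vs reference method) are compared
with:

```sh
musclefat agreement methodA.csv methodB.csv --by level --out report/
```

which writes a CSV of mean (SD), ICC (95% CI), SEM and limits of agreement
per parameter and a Bland–Altman plot per parameter.

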