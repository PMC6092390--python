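# octaquant

Quantification of retinal and choroidal microvascular parameters from
OCT / OCT-angiography images, and cohort-level statistics for staging
diabetic retinopathy (DR).

## What it does, and for whom

OCT angiography renders the retinal capillary network layer by layer
(superficial and deep capillary plexus) as en-face images; structural OCT
B-scans show the choroid beneath. In diabetes the capillary bed remodels
before retinopathy is clinically visible, and a family of scalar imaging
biomarkers tracks that remodelling:

* **FAZ morphometry** — the foveal avascular zone is traced as a polygon;
  its area *A* (mm²), perimeter *P* (mm) and **circularity index**

  $$C = \frac{4\pi A}{P^2} \in (0, 1]$$

  (1 for a circle, lower for irregular contours) quantify enlargement and
  distortion of the capillary-free zone.
* **Vessel density (VD, %)** — the foreground fraction of the en-face
  image after **Niblack auto local thresholding**: a pixel is vessel iff
  $I > \mu_w + k\,\sigma_w - c$ over a $(2r{+}1)^2$ window.
* **Vessel length density (VLD, mm⁻¹)** — the binarized vessels are
  thinned to 1-px skeleton lines; VLD = skeleton length / scan area, a
  caliber-independent measure of the capillary network.
* **Choroidal vascularity index (CVI, %)** — on the subfoveal B-scan
  window (1,500 µm centred on the fovea), CVI = luminal (dark-pixel) area
  / total choroidal area.
* **Cohort statistics** — across the six ordinal severity groups
  (healthy, no DR, mild / moderate / severe NPDR, PDR): quality filtering
  (signal strength index > 60), covariate-adjusted severity trends fit as
  linear mixed models with a per-patient random intercept (both eyes of a
  patient are correlated), and ROC / Youden-index diagnostics with DeLong
  AUC confidence intervals.

Everything is driven by a first-class synthetic-data module: en-face
phantoms with a Fourier-contour avascular zone and a grown vessel network
whose centreline length is known, choroid phantoms with a known luminal
fraction, and six-group cohorts with published group means/SDs — so every
stage is testable against ground truth without clinical images.

The audience is imaging researchers who want a reproducible, scriptable
version of this quantification chain (typically done interactively in
ImageJ) plus the matching statistics.

## Worked example

`examples/04_cohort_statistics.py` generates the default 174-eye
synthetic cohort, filters it, and runs both analyses:

```
cohort: 170 eyes of 107 subjects pass the signal-strength filter

CVI severity trend : -0.72 ± 0.18 % per severity step (p = 5.3e-05, mixed model)
adjusted for age, sex and diastolic BP with a per-patient random intercept

FAZ circularity (deep plexus), no-DR vs DR:
  AUC 0.800 (95% CI 0.696-0.903)
  Youden cutoff 0.62: sensitivity 88.1 %, specificity 62.1 %
  lower values indicate disease: True
```

Reading: the choroidal vascularity index falls by ~0.7 percentage points
per severity step after adjustment; the deep-plexus FAZ circularity index
separates eyes with retinopathy from diabetic eyes without it at AUC 0.80
in this synthetic cohort, with eyes below circularity 0.62 flagged as
diseased. The other examples cover FAZ morphometry (`01`), en-face vessel
quantification (`02`), the CVI (`03`) and the fully reproducible pipeline
run with hashed outputs (`05`).

A thin CLI mirrors the library:

```bash
octa-quant generate --kind enface --out phantoms
octa-quant quantify-enface --image phantoms/enface.png --extent-mm 3 --out result.json
octa-quant cohort-stats --cohort cohort.csv --metrics all --out results/
```

## Layout

```
src/octaquant/
  geometry.py   calibration, polygon ROIs, FAZ morphometry
  vessel.py     Niblack binarization, skeleton, VD / VLD
  choroid.py    subfoveal window, luminal mask, CVI
  stats.py      filtering, adjusted trends, ROC / Youden / DeLong
  phantoms.py   synthetic en-face / choroid phantoms, cohort generator
  io.py         PNG/TIFF, ROI JSON, cohort CSV
  pipeline.py   end-to-end runs with manifest + hashes
  cli.py        octa-quant subcommands
```

See `docs/methods.md` for the models, parameter choices and limitations.
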