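# scmseg

Automated nuclei segmentation for reflectance confocal microscopy (RCM)
images of epithelial tissue, built around a spiking cortical model (SCM)
pulse-coupled neural network, with an object-level neural-network
classifier for false-positive removal, a synthetic image model for
controlled evaluation, and a quantitative evaluation harness.

## The problem

RCM images thick epithelium without stains: nuclei appear as bright-ish
blobs over cytoplasmic backscatter, and their contrast to the background
degrades with imaging depth. Quantities of clinical interest — the
nuclear-to-cytoplasmic ratio (NCR), nuclear area and density — require
segmenting hundreds of low-contrast nuclei per frame, which is impractical
to do by hand at scale. `scmseg` is for researchers who need automated,
reproducible nuclear morphometrics from single-channel grayscale frames
(TIFF/PNG, 8- or 16-bit).

## The method

Every pixel of the normalized image S ∈ [0, 1] is a neuron with internal
activity *U*, dynamic threshold *E* and binary output *Y*, updated per
iteration *n*:

```
U_ij(n) = f · U_ij(n−1) + S_ij · Σ_kl W_ijkl Y_kl(n−1) + S_ij
Y_ij(n) = 1   if U_ij(n) > E_ij(n−1), else 0
E_ij(n) = g · E_ij(n−1) + h · Y_ij(n)
```

with f = 0.928, g = 1.078, h = 1.4 and the 3×3 coupling kernel
W = [0.0125, 0.025, 0.0125; 0.025, 0, 0.025; 0.0125, 0.025, 0.0125].
Each neuron fires at most once; recording the first-pulse iteration per
pixel yields the **time matrix**, in which bright coherent features
(nuclei) occupy early iterations and dim background the late ones.

The pipeline: (1) background removal by a scaled Otsu threshold plus a
contiguous-area filter, defining the active field of view (FOV); (2) SCM
filter passes that darken large early-pulsing areas and brighten small,
round, late-pulsing (nucleus-shaped) objects with gamma corrections;
(3) a final time matrix whose regional minima seed objects that grow by
annexing adjacent pixels of successive pulse iterations, up to area and
eccentricity limits; (4) a one-hidden-layer neural-network classifier over
an 8-feature vector per object (area, eccentricity, extent, solidity,
foreground/background intensity mean and standard deviation), trained on a
70/15/15 split with early stopping, that removes probable false positives.

Evaluation follows an any-pixel object rule (a gold object is detected if
any of its pixels is covered), pixel-level confusion counts over the
active FOV, and the F-measure F1 = 2·s·p/(s+p) of pixel sensitivity s and
specificity p. The synthetic image model renders 750 non-overlapping
circular nuclei of 90 px² (≈8 µm at 0.75 µm/px) as Gaussian intensity
bumps over Gaussian white noise on 1000×1000 px² frames, with the
nuclear-to-background contrast ratio controlled exactly (swept 2.6 → 1.6
to emulate depth).

## Worked example

```python
import scmseg as s

cfg = s.ImageModelConfig(contrast=2.2, seed=42)   # synthetic frame
frame, gt = s.generate_frame(cfg)

clf = s.train_on_synthetic_frames([2.6, 2.2, 1.8], seed=7)
mask, fov = s.segment(frame)
final = s.filter_objects(clf, mask, s.normalize_fov(frame, fov.mask))

rep = s.evaluate(final, gt.label_mask, fov.area)
morpho = s.morphometrics(final, cfg.pixel_scale)
```

Printed output of this exact script:

```
objects segmented:    750
object sensitivity:   1.000
pixel sensitivity:    0.903
pixel specificity:    0.9989
F-measure:            0.948
mean nuclear area:    46.5 um^2
mean diameter:        7.69 um
NCR:                  0.0661
```

All 750 simulated nuclei were detected (object sensitivity 1.0); pixel
sensitivity is lower because detected objects slightly under-cover their
gold footprints; specificity is near-perfect because almost no background
pixels are claimed. The mean recovered diameter (7.69 µm) sits just under
the 8.03 µm equivalent diameter of the nominal 90 px² nucleus, consistent
with conservative growth limits.

The same workflow is available from the shell:

```
scmseg simulate --contrast 2.2 --seed 42 --out sim/
scmseg segment sim/frame.tif --out mask.tif --summary summary.json
scmseg evaluate mask.tif sim/labels.tif --out report.json
scmseg sweep --levels 2.6,2.4,2.2,2.0,1.8,1.6 --replicates 3 --seed 7 --out sweep.csv
```

## Layout

- `src/scmseg/synthetic.py` — synthetic epithelium image model
- `src/scmseg/scm.py` — SCM neuron update and time matrix
- `src/scmseg/pipeline.py` — background removal, filtering, mask growth
- `src/scmseg/classifier.py` — object features and the ANN classifier
- `src/scmseg/metrics.py` — NCR, morphometrics, evaluation, contrast sweep
- `src/scmseg/io.py`, `src/scmseg/cli.py` — formats and the `scmseg` CLI
- `docs/methods.md` — modelling assumptions, parameters and limitations
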