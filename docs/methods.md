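# Methods

This note documents the models, parameter choices and numerical decisions
behind `scmseg`, and what the synthetic-model results do and do not say
about real tissue images.

## Spiking cortical model

The SCM is a simplified pulse-coupled neural network: one neuron per
pixel, three coupled update equations (internal activity *U*, binary
output *Y*, dynamic threshold *E*; see the README for the formulas). The
published coefficients are used unchanged: f = 0.928 (activity decay),
g = 1.078 (threshold growth), h = 1.4 (threshold kick after a pulse), and
the 3×3 coupling kernel W with 0.025 on edge neighbours, 0.0125 on
diagonal neighbours and 0 at the centre.

Choices the network description leaves open, fixed here:

- **Initialisation** — U(0) = 0, Y(0) = 0, E(0) = 1 with the stimulus
  normalized to [0, 1]. Starting the threshold at the top of the intensity
  range makes the brightest pixels fire first, which is what gives the
  time matrix its intensity ordering; E(0) = 0 would fire every neuron at
  n = 1 and collapse it.
- **Within-iteration ordering** — compute U(n), compare against E(n−1),
  then update E(n). This resolves the circular reference between the
  output and threshold equations in the standard way.
- **Fire-once modification** — after a neuron pulses, its output is
  frozen at zero and its U and E are no longer updated. Neighbours
  therefore receive a neuron's coupling contribution in exactly one
  iteration.
- **Boundary handling** — zero padding (out-of-frame neighbours
  contribute nothing).
- **Iteration cap** — 40, with sentinel value 41 for pixels that never
  fire. Because the threshold of a silent neuron grows as g^n while its
  activity saturates at S/(1−f), stimuli below
  min_n g^(n−1)(1−f)/(1−f^n) ≈ 0.268 *never* fire; with the defaults
  every stimulus that can fire at all does so well before iteration 40.
  The never-fire floor is a feature: after normalization, deep background
  ends up at the sentinel and never seeds or joins objects.

## Pipeline

**Background removal.** Candidate background pixels fall below
`otsu_scale` (default 0.5) times the Otsu threshold. A binary opening
(3×3 structuring element, 2 iterations) removes speckle chains first —
dark noise inside tissue can otherwise 8-connect into one huge
"contiguous" region — and only solid candidate components covering > 5%
of the frame *and* touching the border are removed. The remainder is the
active FOV; its pixel count is the denominator basis for NCR and pixel
specificity. A constant image degenerates the histogram: the full frame
is kept with a warning.

**Normalization.** Min–max over the active FOV to [0, 1]; pixels outside
the FOV are zeroed (stimulus-free, hence sentinel in the time matrix).
Note that this stretches a *signal-free* frame's noise across the full
range; the classifier is explicitly trained to recognise the spurious
detections this produces (below).

**SCM filtering.** Only the first 6 pulse outputs are analysed (darker
features pulse later and are irrelevant). Defaults: 2 passes; objects in
iterations {1, 2} with area > 1000 px² are darkened with gamma 1.5;
objects in iterations {4, 5, 6} with area in [30, 200] px² and
eccentricity ≤ 0.85 are brightened with gamma 0.6. Gamma is applied to
the affected pixels only; pulse outputs are disjoint (fire-once), so the
two corrections never collide. All values are config-exposed
(`FilterPolicy`); none are published, and the defaults were chosen to
darken saturated patches and lift dim nucleus-shaped objects on the
synthetic model.

**Mask growth.** Seeds are the regional minima of the final time matrix
(8-connected by default; sentinel pixels excluded; a fully constant
region falls back to its global-minimum level). Each seed object annexes
adjacent unclaimed pixels level by level, under three rules that keep
growth on the nucleus and off the noise:

1. *Strictly successive*: an iteration-t pixel attaches only to object
   pixels that pulsed at t−1 (or were annexed at t). The rings of a
   Gaussian intensity bump pulse in consecutive iterations, so nuclei
   grow naturally; background pixels that happen to pulse late never
   attach to a stale object boundary.
2. *Solid ring*: an annexed pixel needs ≥ 2 source pixels in its
   8-neighbourhood (single-pixel objects are exempt, else they could
   never start growing). Isolated noise rarely offers solid support.
3. *Limits*: annexation that would push an object past `area_limit`
   (default 90 px², the nominal nucleus area) or past the eccentricity
   limit (default 0.9) is undone in full for that level and the object
   frozen. The eccentricity limit is not enforced below 8 px², where the
   moment-matched ellipse is degenerate (2–3 collinear pixels already
   read as eccentricity 1).

Objects never merge (annexation claims only unlabeled pixels), ties go to
the higher label deterministically, and objects below `min_area`
(default 10 px²) are discarded as noise seeds at the end. Eccentricity is
that of the ellipse with matching second central moments (0 = circle,
→ 1 = line), computed in closed form from per-label moment sums for
speed.

## Object classifier

Each object yields 8 features: area, eccentricity, extent, solidity, and
intensity mean/standard deviation over the object and over a background
ring (3 dilation steps of the footprint, minus the pixels of *all*
objects, so neighbours never leak into another object's background).
Degenerate conventions: a single pixel has eccentricity 0, extent 1,
solidity 1; collinear pixels have eccentricity 1.

The classifier is one hidden layer of 10 logistic units. Labeled objects
are split 70/15/15 (stratified, seeded) into training/validation/test;
training stops early after 10 epochs without validation improvement, and
the untouched test split provides the reported accuracy. Features are
standardized with training-split statistics. Objects are kept at
posterior ≥ 0.5. The model serialises to a single JSON file (metadata,
scaler statistics, network weights) and restores without refitting.

For the synthetic workflow, training labels come from ground truth: the
pipeline segments one frame per contrast level, and objects overlapping
any gold nucleus (any-pixel rule) are positives, the rest negatives. One
additional *nucleus-free* frame contributes its spurious detections as
negatives — normalization stretches pure noise into the signal range, and
without such examples the classifier has no concept of a signal-free
field. This generated database stands in for the manually segmented
object database the original workflow used, which is not available.

## Synthetic image model

Frames emulate en-face RCM sections of epithelium: 750 circular nuclei of
90 px² (equivalent diameter 8.03 µm at 0.75 µm/px) placed uniformly at
random with pairwise centre distance ≥ 2⌈r⌉ (no overlap; rejection
sampling with a bounded attempt budget), rendered as truncated 2-D
Gaussian bumps (σ = r/2, so the footprint edge sits at ~2σ) over
Gaussian white noise, on 1000×1000 px² frames. Footprints are the exactly
90 lattice points nearest each centre, so ground-truth areas are exact.

Contrast — mean intensity over nuclear pixels divided by mean intensity
over background pixels — is the control variable. At the reference
contrast 2.0 the background is N(0.25, 0.05²); for other levels the
nuclear signal is scaled down and the background up by equal factors in
log-ratio (the noise σ scales with the background mean). Per-object peak
amplitudes get ±10% multiplicative jitter. Because intensities clip to
[0, 1], the bump amplitude is calibrated by a short fixed point against
the model's own contrast estimator; generated frames realize the
requested contrast to within ±0.005 and are bit-reproducible per seed.
The background statistics and peak histograms of real tissue are not
published; these values are stand-ins constrained only by the realized
contrast ratio.

What the model deliberately omits: cell borders, keratinized regions,
rete ridges, depth-dependent blur, and spatially correlated speckle. Its
background is *white* noise, which makes background suppression easier
than in tissue; passing the synthetic benchmarks therefore demonstrates
correct mechanics and graceful contrast degradation, not tissue-level
performance. Published tissue sensitivities (50–90%, depending on depth
and species) are far below the model's, and nothing here claims to
reproduce them.

## Evaluation conventions

- Object level: a gold object is a TP if ≥ 1 of its pixels is covered by
  any predicted object; a predicted object with no gold overlap is an FP.
  No one-to-one matching: a predicted object spanning two gold objects
  credits both and is itself not an FP.
- Pixel level: TP/FP/FN by set intersection/difference of object pixel
  sets; FP includes stray pixels of object-level-TP predictions; TN is
  the active-FOV area minus TP + FP + FN.
- F-measure: harmonic mean of pixel sensitivity and pixel specificity.
- NCR: total object area divided by the remaining FOV area.
- Mean nuclear diameter: equivalent-disk diameter of the mean area.
- Contrast sweep: per level, `replicates` frames with seeds
  {s, s+1, ...}; metrics reported per replicate and as mean ± sd.

## Problem sizes and determinism

Unit tests run on 256 px frames with 48 nuclei (the native object
density); the full-scale evaluation (classifier training plus an
18-frame sweep at 1000 px) runs in a few minutes on one CPU. Every source
of randomness — placement, noise, jitter, splits, network init — derives
from explicit seeds; identical configuration and seed give bit-identical
frames, masks and reports.

## Known limitations

- The filter-policy and growth-policy constants are engineering choices
  validated on the synthetic model only; tissue work should expect to
  re-tune them (they are all config-exposed).
- Pixel sensitivity saturates below 1 by construction: growth stops at
  the nominal area, so the dimmest outer ring of each nucleus is often
  left uncovered. Object detection is unaffected.
- The classifier generalises across the contrast range it was trained
  on; applying it far outside (or to other magnifications/pixel scales)
  requires retraining.
- Frames are processed independently: no 3-D linking of nuclei across a
  depth stack.
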