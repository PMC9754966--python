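# Methods

## Problem

Type 1 nonexudative macular neovascularization (neMNV) in AMD shows on
structural OCT as the **double-layer sign (DLS)**: a shallow, irregular,
broad elevation of the retinal pigment epithelium (RPE) away from Bruch's
membrane, with a visible separation between the two.  Ordinary **drusen**
also elevate the RPE but as compact domes *without* a separation.  This
package implements an end-to-end detector: a transformer semantic
segmenter labels DLS and drusen pixels on every B-scan of a volume, the
per-B-scan masks are collapsed into an en-face map, and the eye is called
MNV-positive when its largest connected DLS blob is large enough.

## Phantom generator

No clinical volumes ship with the package; all experiments run on a
seeded synthetic phantom that renders the discriminative cues a human
grader uses:

* a layered retina — dark vitreous, mid-gray neurosensory retina, a bright
  RPE band (the brightest structure, which retina-centred cropping relies
  on), a thin Bruch's membrane line, and an exponentially attenuating
  choroid;
* drusen: dome-shaped elevations (`(1 - r^2)^p` profile, default p = 0.5)
  between RPE and Bruch, diameter 250-800 um (medium-to-large confluent
  drusen; only drusen > 63 um are annotated in the emulated protocol,
  enforced as a validated lower bound), height 70-130 um, medium interior
  reflectivity (0.50);
* DLS: broad (1200-2500 um) shallow (40-100 um) elevations with an
  irregular roughness-modulated profile and a *hyporeflective* interior
  (0.12) — the RPE-Bruch separation.  A validated invariant keeps every
  admissible DLS flatter (height/footprint) than every admissible druse.
  The default lesion statistics sit at the large end of the clinical
  ranges; at the desk pitches below this keeps every lesion at least
  ~1.5 decoder strides thick in both axes, i.e. resolvable by the
  segmenter at all (see "Desk-scale geometry");
* optional geographic atrophy for late-AMD eyes: the RPE band drops to
  retina-level reflectivity and the choroid beneath brightens
  (hypertransmission gain 1.9);
* multiplicative gamma speckle (shape 8, mean 1) followed by a light axial
  Gaussian blur (sigma 0.8 px).

Ground truth is exact by construction: every voxel between the elevated
RPE and Bruch's membrane is labelled DLS (class 1) under a separation and
drusen (class 2) under a dome, and the eye label is *defined* as "contains
at least one DLS voxel".  The generator records its own geometry (RPE and
Bruch surfaces) so tests can audit label soundness independently of the
renderer.

**Scales.**  The full profile matches the emulated acquisition: 500
B-scans x 1536 depth x 500 A-scans over 6 x 6 mm, 12 um lateral pitch, and
an assumed 1.95 um axial pitch (the acquisition's axial pitch is not
public; the 3-mm window is a modelling assumption).  The desk profile used
throughout the tests is 64 x 256 x 128 over the same 6 x 6-mm footprint
with a 2.5 um axial pitch (~0.64-mm window around the outer retina).  The
finer-than-proportional axial pitch is deliberate: it keeps lesion
thickness *in pixels, relative to the segmenter's patch size* in the same
regime as the full-scale recipe (see "Desk-scale geometry" below).

The **easy benchmark** (`PhantomConfig.desk(easy=True)`) is the
high-contrast, speckle-free condition used by the learning-capacity tests:
speckle off and a widened reflectivity ladder (vitreous 0.02, retina 0.40,
RPE 1.0, Bruch 0.62, choroid 0.16; DLS interior 0.06, drusen interior
0.62), so that segmentation scores reflect the model rather than noise or
ambiguous gray levels.

**What the phantom does not model:** real speckle correlation, vessel
shadows, motion artifacts, segmentation-confounding pathology (fluid,
hyperreflective foci), inter-grader label noise, and anatomical variety
beyond smooth surface undulation.  Passing the phantom benchmarks
demonstrates that the pipeline's machinery — geometry, losses, projection,
classification, statistics — is correct and that the architecture can
learn these morphologies; it says nothing about clinical performance.

## Preprocessing

B-scans are cropped axially to half their depth with the window centred on
the intensity-weighted centroid of the brightest smoothed band (the RPE),
clamped to the image; a featureless image falls back to a central crop.
The grayscale crop is triplicated into three identical channels and
normalised with mean 0.5 / std 0.5 per channel, mapping [0, 1] to [-1, 1].
Training-time augmentation resizes by a ratio drawn from U(0.5, 2.0)
(bilinear for the image, nearest-neighbour for the mask so no labels are
invented), flips left-right with probability 0.5, then randomly crops or
centre-pads to the square input size; padded mask pixels carry the ignore
label 255 and are excluded from the loss.  Inference is deterministic:
centre-crop, resize to the input size, triplicate, normalise.

## Segmenter

A plain ViT encoder: non-overlapping square patches, flattened and
linearly projected; learnable position embeddings added once; then
pre-norm transformer layers (multi-head self-attention, 2-layer GELU MLP,
residual connections around both, layer norm before each).  There is no
class token — segmentation decoding needs exactly one embedding per patch.
The decoder is a pointwise linear layer to per-patch class logits,
reshaped to the patch grid, bilinearly upsampled to the input size, and
softmaxed over classes; at inference argmax (ties to the lowest class
index) yields the label map.  Position embeddings transfer across input
resolutions by bilinear resampling of the embedding grid (align-corners
convention, so a linear ramp stays a linear ramp).

The full-scale configuration is 12 layers, embedding 768, 12 heads, patch
16 on 512 x 512 inputs.  The desk configuration is 4 layers, embedding
128, 4 heads, patch 8 on 128 x 128 inputs.

**Desk-scale geometry.**  The patch-logit grid is the decoder's spatial
resolution.  At full scale it is 32 x 32.  Keeping patch 16 at a 128 px
input would leave an 8 x 8 grid, and direct optimisation of patch logits
against ground-truth masks (the representational ceiling, with no encoder
in the loop) shows such a grid cannot exceed ~0.13 lesion IoU on the thin
sub-RPE bands — the task would be impossible regardless of training.
Patch 8 (16 x 16 grid) plus the 2.5-um desk axial pitch restores the
lesion-thickness-to-patch ratio of the full-scale recipe.

**Training.**  Per-pixel cross-entropy excluding ignore pixels.  The
reference recipe is SGD with momentum 0.9, base learning rate 1e-3, and a
polynomial decay `lr = base * (1 - step/total)^0.9` stepped per update —
a fine-tuning recipe that presumes pretrained weights.  This package
trains from scratch (no downloads), and at desk scale SGD is far from
convergence within any reasonable CPU budget, so the desk recipe
(`TrainConfig.desk_recipe()`) uses the adaptive-moment optimizer under the
same polynomial schedule, plus inverse-frequency pixel reweighting
(weight 1/sqrt(batch class frequency)): lesions are <1% of pixels and an
unweighted from-scratch run spends its whole budget predicting
background.  Both options are exposed in `TrainConfig`; the SGD default
reproduces the reference recipe.  Initialisation is truncated normal
(std 0.02) with zero-initialised decoder head, so the untrained model
predicts the uniform distribution and the initial loss is exactly ln 3 on
balanced labels.

## U-Net baseline

A classic symmetric U-Net ((conv3x3, ReLU) x2 per level, 2x2 max-pool
down, nearest-upsample + skip concatenation up, 1x1 head; 4 levels / 32
base filters at full scale, 3 levels / 8 filters at desk scale) trained
on single-channel [0, 1] inputs with Adam, cross-entropy, spatial
(whole-channel) dropout, and shift (±5%) / horizontal-flip / rotation
(±10 deg) augmentation.  The learning rate decays per update as
`lr_t = lr0 / (1 + d t)` with `d = lr0 / epochs`.  Both models are scored
with the identical pooled-IoU code path; the ViT-minus-U-Net difference is
reported without asserting a sign (it is data-dependent).

## En-face classification

A column of the prediction volume becomes a DLS pixel of the en-face map
if it contains any DLS voxel, else drusen if any drusen voxel, else
background (DLS precedence — lesion footprints project solid).  The map is
downsampled by exact area-fraction block averaging (fractional block edges
handled by linear interpolation of cumulative sums); a target pixel takes
the DLS label when the DLS fraction of its source block is >= 0.5, which
deletes isolated single-pixel noise — the stated purpose of the rescale.
Native 500 x 500 maps go to 128 x 128; desk 64 x 128 maps go to 32 x 32
(upscaling is refused).  Connected DLS components use 8-connectivity by
default (4 available); the eye is positive iff the largest component
strictly exceeds the threshold — 65 px at the 128 x 128 scale.  On a
labelled validation cohort, `threshold_sweep` recomputes the
misclassification count at every integer threshold and selects the floor
midpoint of the *widest* contiguous minimal-error run, a deterministic
version of "centre of the lowest-error interval".

## Statistics

* Sensitivity/specificity/PPV/NPV are exact `Fraction`s; rounding (half
  away from zero) happens only at display.  Undefined rates (zero
  denominator) are reported as undefined, never 0.
* ROC over all distinct score thresholds; trapezoidal AUC (equal to the
  pairwise Mann-Whitney probability); 95% CI by seeded stratified
  bootstrap (2000 resamples by default) since the reference does not print
  its CI method.
* Cohen's kappa from marginal products, bands: < 0.4 poor, 0.4-0.75
  (inclusive both ends) fair to good, > 0.75 excellent; identical constant
  raters give an undefined kappa, reported as such.
* Association: two-sided Fisher exact test by default (small cells);
  chi-square with continuity correction behind a flag.
* IoU is pooled over images per class; classes absent from both prediction
  and truth are skipped; the headline number is the mean over the two
  lesion classes.

## Problem sizes used by the test suite and acceptance script

Desk-scale phantom cohorts: 9 training eyes (5 MNV-positive), 5 validation
eyes (3 positive), and an 11-14-eye classification cohort, each eye
64 x 256 x 128 voxels; ~7 B-scans sampled per eye for segmentation
training (~63 pairs).  The desk ViT recipe runs 60 epochs at batch 8
(~480 updates), about 3-4 minutes per seed on one CPU; the test suite
trains three seeds and accepts on the median.  The U-Net comparison uses
a 20-epoch run with the same pixel reweighting, so the reported
ViT-minus-U-Net difference reflects architecture rather than
class-imbalance handling.  These sizes were chosen so a single-CPU run of the whole
suite stays comfortable while every pipeline stage is exercised end to
end.  Model parameters and activations are float32; the gradient-check
tests build float64 models, where finite differences are meaningful at
1e-6 step sizes.

## Known limitations

* The phantom's lesions are smooth parametric surfaces; real DLS/drusen
  boundaries are noisier and their reflectivity overlaps more.
* From-scratch desk training is not the reference training condition (no
  large-scale natural-image pretraining, adaptive optimizer, pixel
  reweighting); clinical IoU/AUC figures are not reproducible here and are
  not targets.
* The full-scale profile (500 x 1536 x 500 float32) needs ~1.5 GB per eye;
  generating full cohorts requires memory planning.
* Kappa p-values are not computed (the agreement statistic and its bands
  are); association p-values come from the 2x2 Fisher test.
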