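# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of the `nbihisto` pipeline. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

The unit of analysis is an annotated NBI colonoscopy still: an RGB raster, a
binary lesion annotation mask drawn by an endoscopist, a lesion-level
histology label in {LGD, HGD, SMs, SMd}, and optionally an effective
region-of-interest mask (for endoscope frames with dark borders). The
pipeline learns a patch-level 7-category classifier and reduces its
per-patch predictions to one histology call per image. Lesion *detection*
is out of scope: the annotation mask is an input.

## Quality masks

Blackout and halation are per-pixel intensity rules on 8-bit channels:
blackout ⇔ red < 50, halation ⇔ green > 250, both strict. The effective
region is the ROI (full frame when absent) minus both masks. These rules
are deliberately local — each pixel's flag depends only on its own channel
values — which makes them idempotent and exactly testable.

## Focus score

A patch's focus score is the fraction of its non-DC spectral energy above
an ideal radial high-pass cutoff:

- the patch (a single channel; **green** by default, since the narrow blue/
  green NBI illumination concentrates signal there) is mean-subtracted and
  tapered with a 2-D Hann window;
- the 2-D DFT power spectrum is split at radial frequency
  `cutoff × Nyquist`, with `cutoff = 0.0625` and Nyquist = 0.5
  cycles/sample;
- score = high-band energy / total non-DC energy, defined as 0 for constant
  patches.

The Hann taper matters: without it, spectral leakage from strong
non-periodic low-frequency content (illumination gradients) masquerades as
high-frequency energy, and heavily defocused patches can still score ~0.08.
With the taper, defocused phantom patches score ~0.001–0.004 against
~0.4–0.7 for sharp ones. The energy-conservation invariant (low + high =
total non-DC, to 1e-6 relative) holds for the windowed spectrum.

The score is an energy *fraction* rather than a pixel count of the filtered
response: it is deterministic, scale-invariant (doubling contrast does not
change it) and directly testable against closed-form spectra (a period-2
checkerboard scores exactly 1). The in-focus decision is `score ≥
threshold` with a default threshold of **0.02**, calibrated on phantom
fixtures where it sits two orders of magnitude above defocused scores and
an order of magnitude below sharp ones; it is exposed in the configuration
because real endoscopes will need their own calibration.

## Patch grid, admission, categories

Patches are 128 × 128 px, cut at origins `(r, c)` with both coordinates
multiples of the 32 px stride, in raster order; windows are half-open
`[r, r+128) × [c, c+128)`, 0-based. A window is admitted iff its blackout
fraction ≤ 0.10 **and** halation fraction ≤ 0.05 (exclusion is strict —
"more than" / "exceeding"). Fractions are taken over the window's
intersection with the ROI, not a fixed 128², so border windows are judged
on their usable area; windows with zero ROI overlap are skipped silently
during manifest building.

Category assignment: lesion membership is decided by the lesion mask's
coverage of the window's *effective* pixels against a threshold (default
**0.5**, configurable — boundary-straddling windows have no canonical
label, so the choice is explicit). In-focus lesion windows take the image's
histology label (1–4), in-focus background windows take 0, and out-of-focus
windows take 6 (lesion) or 5 (background).

## Classifier and cross-validation

The classifier is a contract: `predict(patches) → categories 0–6`,
deterministic at inference. Three backends ship:

- **oracle** — answers with the true category of each window; the structural
  upper bound that lets the aggregation stage be tested in isolation;
- **constant** — a fixed category; the degenerate baseline;
- **spectral** (default, trainable) — multinomial logistic regression (with
  feature standardization) on a 12-dimensional feature vector per patch:
  per-channel means and standard deviations, plus log-energies of six
  geometrically spaced radial spectral bands of the green channel. The
  bands capture each class's dominant texture frequency and the collapse of
  high-frequency energy under defocus; the chroma statistics capture the
  class color. It trains in seconds on one CPU.

The reference full-scale configuration — a ResNet50-class residual network
trained from scratch on 224 × 224 bilinear-resized patches with Adam,
cross-entropy loss, 50 epochs, batch size 256, learning rate 5 × 10⁻⁵ —
ships as `REFERENCE_TRAIN_CONFIG` and is honored by the contract, but no
deep-learning framework is imported: any conforming backend can be plugged
in. Pixels are scaled to [0, 1] by division by 255 with no mean/std
normalization (training from scratch leaves no canonical statistics).

Cross-validation is stratified k-fold (k = 3) at the **lesion** level by
default: all frames of one lesion share a fold, preventing near-duplicate
frames of the same lesion from leaking across the train/validation split.
Image- and patch-level splitting are available via configuration for
fidelity experiments. The fold builder sorts units before seeded shuffling
(order-invariance), deals each label's units evenly, and sends remainders
to the currently smallest folds — per-label fold counts differ by at most
one, and a 210-lesion cohort with label counts (53, 120, 20, 17) splits
70/70/70. Every unit is validated exactly once across the k runs.

## Image-level aggregation

For one image, the union mask Mᵢ (i = 0…4) is the pixel-set union of the
128 × 128 footprints of all patches predicted as in-focus label i,
intersected with the effective region. Predicted categories 5 and 6
contribute to no union mask — only in-focus evidence drives the image call.
The effective annotation mask X is the lesion mask minus blackout and
halation, the same subtraction applied to Mᵢ so numerator and denominator
are commensurate. The image is classified as argmaxᵢ IoU(X, Mᵢ).

Numerical conventions: IoU of two empty masks is 0; ties in the argmax
break toward the larger label index (clinical conservatism — when evidence
is exactly balanced, call the more severe grade); an argmax of 0 is
reported as a background/no-lesion call rather than folded into a lesion
class. Union masks of distinct labels may overlap spatially (the stride is
smaller than the patch), and the implementation makes no partition
assumption. Footprints are full 128 × 128 areas, not outlines — outline
footprints would make every IoU degenerate.

## Metrics

Per-category fold accuracy is correct/total; the averaged accuracy is the
unweighted mean over folds. The image-level confusion matrix has ground
truth on rows and predictions on columns; recallᵢ = cᵢᵢ/rowᵢ, precisionᵢ =
cᵢᵢ/colᵢ, F1 the harmonic mean, overall accuracy = trace/total. Report
strings round half-up to 3 decimals (matching the convention of clinical
reports; note that Python's built-in rounding is banker's) while full
precision is kept internally. Precision of a never-predicted class is NaN
with a warning, not 0 — a silent zero would deflate or inflate macro
summaries invisibly.

## Phantom generator

The generator emulates the *structure* of an annotated NBI cohort, not its
appearance. Defaults, chosen once as the study conditions for all tests:

- **Frame** 384 × 384 px → a 9 × 9 patch grid at 128/32.
- **Lesion** an ellipse strictly inside the frame; random geometry per
  image draws semi-axes from [60, 105] px so that at least one grid window
  reaches 50% lesion coverage.
- **Textures** per class: two randomly oriented sinusoids at a
  class-specific period (background 24 px; LGD 16, HGD 10, SMs 6, SMd 4 —
  all above the 6.25%-Nyquist cutoff, so unblurred patches are in focus)
  with amplitude 25, on a class-specific base color, plus a shared
  low-frequency illumination field (period 128 px, amplitude 25) and
  additive Gaussian noise (σ = 2). The periods loosely mimic the increase
  of surface/vessel pattern granularity with grade; separability is
  deliberately strong so CPU-scale models succeed.
- **Artifacts** two blackout disks (radius 16–40 px) at RGB (20, 20, 20)
  and one halation disk (radius 10–24 px) at (255, 255, 255); all other
  pixels are clipped to [55, 245], so the quality module recovers injected
  artifacts with exact pixel agreement. A random 128–224 px rectangle is
  Gaussian-blurred with σ = 12 — strong enough to pull the focus score of
  fully covered patches well below the 0.02 threshold — creating genuine
  BG-oof and L-oof training material.
- **Cohorts** are reproducible per seed via spawned generator streams; each
  phantom image is its own lesion (one frame per lesion).

What the phantoms do **not** model: photorealistic mucosal appearance,
magnification strata, multiple frames per lesion, mixed-grade (heterogeneous)
lesions, motion blur, or annotation noise. Passing phantom tests therefore
demonstrates the correctness of the pipeline's mechanics — masking,
admission, labeling, fold hygiene, aggregation arithmetic — and the
learnability of cleanly separable classes, not clinical-grade classifier
performance.

## Problem sizes

The cross-validated learning benchmark uses 60 phantoms (15 per label) with
artifacts and defocus, three folds, and the spectral backend — about 3,900
admitted patches — chosen as the smallest cohort at which every category is
well represented in every training split. The oracle end-to-end check uses
20 artifact-free phantoms. Union-mask/IoU equivalence against the per-pixel
brute-force reimplementation runs on 200 randomized 40 × 40 fixtures with
16 px patches.

## Known limitations

- The trainable reference backend is a global-feature model: it cannot
  express the spatial pattern analysis a convolutional network performs,
  and on real NBI data a full-scale backend behind the same contract would
  be required.
- The in-focus threshold (0.02) and the coverage threshold (0.5) are
  phantom-calibrated defaults; clinical deployments must recalibrate.
- Out-of-focus categories on phantoms are the hardest classes (defocus
  erases exactly the spectral features that separate textures, and blurred
  lesion/background chroma mixes near boundaries); this mirrors their role
  as non-diagnostic buckets — they are excluded from image-level evidence.
- An all-zero IoU vector (an image with no in-focus evidence) resolves, by
  the severity tie-break, to the most severe label; images that produced no
  admissible patches at all are excluded from the image-level tally instead.
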