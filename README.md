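# nbihisto

Patch-based multi-class histologic classification of narrow-band-imaging
(NBI) colonoscopy still images, with image-level calls by union-mask
IoU-argmax aggregation.

NBI endoscopy renders the mucosal surface and vascular pattern of colorectal
lesions at high contrast, and the visual granularity of those patterns tracks
both the grade of dysplasia and the depth of submucosal invasion — the
distinction that decides between endoscopic resection and surgery. This
package implements the full analysis pipeline for classifying an annotated
lesion still into **LGD** (low-grade dysplasia), **HGD** (high-grade
dysplasia / mucosal carcinoma), **SMs** (superficial submucosal invasion,
< 1000 µm) or **SMd** (deep submucosal invasion, > 1000 µm):

1. **Quality masking** — blackout pixels (red < 50) and halation pixels
   (green > 250) are removed from the usable ("effective") region.
2. **Patch extraction** — 128 × 128 px windows on a 32 px stride over the
   effective region of interest; windows with more than 10% blackout or more
   than 5% halation are excluded.
3. **Focus triage** — each patch is scored by the fraction of its non-DC
   spectral energy above an ideal radial high-pass cutoff at 6.25% of the
   Nyquist frequency; in-focus patches are labeled background (0) or by
   their lesion's histology (1–4), out-of-focus patches become categories
   5 (BG-oof) and 6 (L-oof).
4. **Patch classifier** — a pluggable 7-class contract evaluated by
   lesion-stratified three-fold cross-validation. The shipped reference
   configuration is a ResNet50-class network (224 × 224 inputs, Adam,
   cross-entropy, 50 epochs, batch 256, lr 5 × 10⁻⁵); the CPU-light
   trainable backend used by the test suite is a logistic-regression model
   on radial spectral-band and chroma features.
5. **Image-level aggregation** — for each image, the union masks M₀…M₄ of
   footprints of patches predicted as the in-focus labels are intersected
   with the effective annotation mask X, and the image is classified as

   argmaxᵢ IoUᵢ, IoUᵢ = |X ∩ Mᵢ| / |X ∪ Mᵢ|, i = 0…4,

   with ties broken toward the more severe label.
6. **Metrics** — per-category fold accuracies with unweighted averaging, and
   the image-level confusion matrix with per-class recall, precision, F1 and
   overall accuracy (reported half-up at 3 decimals).

Because clinical NBI datasets are private, the package includes a **phantom
generator**: synthetic frames whose elliptical lesions carry class-distinct
texture frequencies and chroma, with injected blackout/halation blobs and
defocus regions rendered at exactly recoverable values, so every stage of
the pipeline is testable end-to-end with known ground truth.

## Worked example

```bash
nbihisto simulate phantoms --n-per-class 3,3,3,3 --seed 7 --artifact-free
python - << 'EOF'
import yaml, pathlib
pathlib.Path("oracle.yaml").write_text(yaml.safe_dump({"backend": "oracle"}))
EOF
nbihisto run phantoms out --config oracle.yaml
```

prints:

```
Patch-level fold validation accuracy
Category  Fold1 total  correct  acc    Fold2 total  correct  acc    Fold3 total  correct  acc    Averaged
BG        268          268      1.000  257          257      1.000  279          279      1.000  1.000
LGD       10           10       1.000  12           12       1.000  7            7        1.000  1.000
HGD       20           20       1.000  17           17       1.000  6            6        1.000  1.000
SMs       6            6        1.000  17           17       1.000  12           12       1.000  1.000
SMd       20           20       1.000  21           21       1.000  20           20       1.000  1.000

Image-level confusion matrix (rows truth, cols predicted)
truth\pred  BG  LGD  HGD  SMs  SMd  total  recall
BG          0   0    0    0    0    0      -
LGD         0   3    0    0    0    3      1.000
HGD         0   0    3    0    0    3      1.000
SMs         0   0    0    3    0    3      1.000
SMd         0   0    0    0    3    3      1.000
Overall accuracy: 1.000
image-level accuracy: 1.000
```

(plus a warning that BG precision is undefined — no image was truly or
predictedly background, so that column is empty by construction).

With the oracle backend (perfect patch predictions) every lesion's label is
recovered by the IoU-argmax aggregation — the structural upper bound of the
pipeline. Replacing `backend: oracle` with the default `spectral` backend
trains the light classifier per fold instead; on a 60-image phantom cohort
with injected artifacts it reaches an image-level accuracy of about
0.97–0.98. The same Python API is available programmatically:

```python
from nbihisto import phantom, pipeline, PipelineConfig

cohort = phantom.generate_set([15, 15, 15, 15], seed=0)
result = pipeline.cross_validate(cohort.images, PipelineConfig())
print(result.image_level_accuracy)   # 0.983 at seed 0
print(result.report.render())
```

The classifier contract is pluggable: any object with a
`predict(patches) -> categories` method over the 7 categories can stand in
for the shipped backends, so a full-scale convolutional model can be dropped
in without touching the rest of the pipeline.

## Layout

- `src/nbihisto/quality.py` — blackout/halation/effective masks, spectral focus score
- `src/nbihisto/patching.py` — strided grid, admission rules, category assignment
- `src/nbihisto/model.py` — classifier contract, backends, stratified folds, resize
- `src/nbihisto/aggregation.py` — union masks, IoU, argmax image calls
- `src/nbihisto/metrics.py` — fold accuracies, confusion matrix, derived metrics
- `src/nbihisto/phantom.py` — synthetic ground-truthed frame generator
- `src/nbihisto/pipeline.py`, `cli.py`, `config.py`, `io.py` — orchestration,
  CLI (`nbihisto`), YAML config, dataset layout

See `docs/methods.md` for the modeling choices, parameter defaults and known
limitations.
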