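# plumvision

Multi-defect classification of green plums (*Prunus mume*) from single-fruit
RGB photographs.  Surface condition determines what a plum can become —
preserves, extract, wine — and hand sorting is slow and inconsistent, so the
package implements a complete machine-vision grading pipeline into five
classes: **rot, rain spot, scar, crack, normal**, ordered by severity
(rot > crack > scar > spot) so that a fruit with several defects takes the
most severe label.

The pipeline:

* **Preprocessing** — deterministic background cropping: 11×11 Gaussian
  smoothing → grayscale → adaptive mean-threshold binarisation → Laplacian →
  Canny → minimal bounding rectangle of the largest edge component →
  bilinear resize to 100×100.
* **Dataset** — severity-priority labeling, per-class 4:1 train/test split
  on original images, then a 10× augmentation (identity, 45°-step rotations,
  horizontal and vertical mirror) of both sides.
* **Synthetic data** — a procedural generator of plum-like images with
  class-specific defect morphology (large irregular blob, speckles, sharp
  patches, thin cracks), fully determined by (seed, class, index), so the
  whole stack is testable without photographs.
* **Model** — a 16-weight-layer VGG variant: 13 conv layers (all 3×3, each
  with batch normalisation and ReLU), 5 max-pool stages, adaptive average
  pooling, fully connected 1024–1024–5.  Pure NumPy engine with verified
  hand-written backward passes.
* **w-softmax loss** — class weight rows are L2-normalised and each negative
  weight is biased toward the positive one,
  `w_i' = (γ·w_c + w_i)/‖γ·w_c + w_i‖`, widening decision margins; γ = 0 is
  exactly softmax cross-entropy.
* **SWA optimizer** — momentum SGD under a cyclic learning rate
  `α(i) = (1−t(i))·α1 + t(i)·α2`, `t(i) = (mod(i−1,c)+1)/c`, averaging the
  weights at the end of each cycle (`w_swa ← (w_swa·n + w)/(n+1)`) and
  rebuilding batch-norm statistics for the averaged model.
* **Evaluation** — 5×5 confusion matrix (canonical order rot, spot, scar,
  crack, normal) and per-class recall / precision / F1 with macro averages.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

Evaluate the published test-set confusion matrix that ships with the
package (2500 augmented test images):

```sh
$ plumvision evaluate --fixture reported
        rot  spot  scar  crack  normal
rot     794     0     6      0       0
spot      3   744    19      1      33
scar     30     5   236      9       0
crack    17    10     8    125       0
normal    0    16     4      0     440
rot      recall 0.9925  precision 0.9408  f1 0.9659
spot     recall 0.9300  precision 0.9600  f1 0.9448
scar     recall 0.8429  precision 0.8645  f1 0.8535
crack    recall 0.7812  precision 0.9259  f1 0.8475
normal   recall 0.9565  precision 0.9302  f1 0.9432
macro recall 0.9006  accuracy 0.9356
```

Every number is integer arithmetic on the counts: rot recall is 794/800 =
99.25%, scar precision 236/273 ≈ 0.86, and 30/280 = 10.7% of scarred fruit
are misjudged as rot.

A desk-scale end-to-end run (generate synthetic plums → preprocess → split →
train a reduced-width network with SWA + w-softmax → evaluate):

```sh
$ plumvision run --config examples/desk.yaml --out runs/desk
```

writes `runs/desk/eval/metrics.json` and `confusion.csv`; every artifact
records the configuration hash and seed that produced it.  The same stages
are importable functions (`plumvision.pipeline`).

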