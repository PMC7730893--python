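# Methods

`plumvision` classifies green plums (*Prunus mume*) into five surface
conditions — rot, rain spot, scar, crack, normal — from single-fruit RGB
photographs.  This note records the models, the numerical choices, and the
limits of what the shipped tests demonstrate.

## Preprocessing

A raw photograph is reduced to a 100×100 background-free crop by a fixed,
deterministic chain:

1. 11×11 Gaussian smoothing (per channel; σ = 0.3·((k−1)/2 − 1) + 0.8,
   reflective borders),
2. luminance grayscale (0.299 R + 0.587 G + 0.114 B, rounded to 8 bit),
3. adaptive mean-threshold binarisation: a pixel is foreground when it
   exceeds the mean of its `block_size` neighbourhood by more than
   `offset` grey levels (defaults 51 and 5).  For ring-lit fruit on a dark
   background this marks a band along the inside of the fruit contour; a
   constant image produces an empty mask,
4. hole filling, so the fruit becomes a solid region whose only contour is
   the outer one,
5. 3×3 Laplacian filtering; the Canny detector (thresholds 50/150 on the
   gradient magnitude) then runs on the absolute Laplacian response, since
   Canny expects a non-negative intensity image,
6. the minimal axis-aligned bounding rectangle of the largest connected
   edge component (8-connectivity; ties broken by smallest column, then
   smallest row),
7. bilinear crop-resize of the original RGB to 100×100 (aspect ratio not
   preserved).

Only the 11×11 kernel is canonical; block size, offset and the Canny
thresholds are package defaults chosen so that the chain recovers the
analytic bounding box of synthetic ellipses to within 2 px per side (100/100
random fixtures) and the fruit box on ≥ 98% of generated plum images.  All
parameters are exposed in the configuration.  Coordinates are 0-based;
boxes are half-open.

## Dataset semantics

Severity ranks are rot > crack > scar > rain spot > normal; an image with
several defects takes the most severe label.  The canonical class order for
every matrix and report is `[rot, spot, scar, crack, normal]`.

Augmentation expands each image into exactly 10 variants: identity, the
seven 45°-multiples rotations (45°…315°), the horizontal mirror, and the
vertical mirror.  Axis-aligned members are exact pixel permutations; the
45° family resamples bilinearly with symmetric padding.  The scheme is
pluggable (a list of tag/transform pairs) because the prose description of
"mirroring plus every 45° rotation, ×10 in total" admits more than one
10-member reading.

Splitting is 4:1 per class on *original* images, before augmentation, so no
variant of a held-out original can leak into training.  The train side
receives round(0.8·n) originals.  Published per-class counts that deviate
from the exact ratio (rot: 310/80 of 390) are reproduced through explicit
per-class overrides.  Both sides are augmented after splitting; test
metrics are therefore over augmented test images (row sums 800, 800, 280,
160, 460).

## Synthetic data

No photograph collection is distributed, so a procedural generator renders
plum-like images: an ellipsoidal green fruit (semi-axes 28–36% of the image
side) with Lambertian-style radial shading on a near-black background
(level 16), Gaussian pixel noise (σ = 2.5), and class-specific defects —
one large irregular dark-brown blob (9–16% of the fruit area) for rot, one
or two sharp-edged patches (1.5–4% each) for scar, a thin random-walk
polyline (width ≤ 3 px) steered to stay inside the fruit for crack, 10–40
small speckles for rain spot, and clean skin for normal.  An optional stem
stub (off by default) reproduces the stem-versus-scar confusion failure
mode as a documented experiment.  Every image is a pure function of
(seed, class, index).

The generator's acceptance bar is separability by a fixed pixel-statistics
rule (dark-area fraction, component count, component shape): ≥ 90% correct
at default contrasts.  The synthetic classes are deliberately *easier* than
photographs — no specular highlights, no stems by default, no pose or
colour variation between fruits beyond mild jitter — so passing tests
demonstrate that the pipeline, network, loss and optimizer function and
interact correctly, not that photographic accuracy would be reproduced.

## Network

A VGG-16-layout classifier: 13 convolutional layers (all 3×3, stride 1,
zero padding), each followed by batch normalisation and ReLU, five 2×2
max-pool stages, adaptive average pooling to a 1×1 grid, and three fully
connected layers 1024–1024–5.  The adaptive pool makes the fully connected
dimensions independent of input resolution (any input ≥ 32×32).  The final
layer is bias-free and exposes its weight matrix to the loss.  The 1×1 pool
grid keeps the first fully connected layer at 512×1024 weights, consistent
with the design goal of a small classifier head; the grid is configurable.
A `width_multiplier` scales all channel and hidden widths for desk-scale
experiments.  There is no dropout; batch normalisation and the loss's
margin act as the regularizers.  Initialisation is He-normal; weights can
optionally be loaded from a checkpoint (e.g. ImageNet-derived), never
required by tests.

The engine is a self-contained NumPy implementation (im2col + BLAS matmul
convolutions, hand-written backward passes, finite-difference-verified),
single-threaded and deterministic.

## w-softmax loss

All class weight rows are L2-normalised.  For a sample of true class c each
negative weight is biased toward the positive one,

    w_i' = (γ w_c + w_i) / ‖γ w_c + w_i‖   (i ≠ c),

and the cross-entropy is taken over the logits [w_c·x, {w_i'·x}].  γ = 0
recovers plain softmax cross-entropy exactly (loss and gradients, verified
to 1e-8); γ → ∞ drives every biased negative onto w_c.  The gradient of
the mean loss with respect to both the features and the raw weight matrix
is computed in closed form; because the loss depends on the weights only
through their directions, the raw-weight gradient is tangential, so weight
norms change only through weight decay.  The default is γ = 1.

Two deliberate departures from a literal transcription:

* **Negative-bias floor ("guard", training only).**  The bare loss has a
  degenerate optimum on separable data: every biased negative logit
  contains the term γ·(w_c·x)/‖γw_c + w_i‖, so driving *all* cosines
  equally negative (features collapsing to a single point anti-aligned
  with the mean weight direction, with unbounded norm) sends the loss to
  zero without the classes separating — we observed exactly this (training
  loss 0, chance accuracy).  During training the biased negative logit is
  therefore floored at the unbiased one.  The floor is inactive at γ = 0
  and throughout the loss's intended operating regime (positive-class
  cosine positive), and the unguarded formula remains the default of the
  public loss functions.
* **Cosine-head inference.**  A head trained under this loss is a cosine
  classifier; prediction scores features against the unit-normalised
  weight rows.  Raw-logit argmax would rescale each class by an arbitrary
  (initialisation-determined) weight norm.

The probability map (γ-biased softmax) is implemented exactly as published;
the printed companion equation for the error probabilities reuses the
correct-class numerator, which cannot normalise, so the error probability
of class i uses exp(‖x‖cos θ_i′) over the same denominator — the unique
reading with Σp = 1.

## SWA optimizer

Momentum SGD (momentum 0.9, weight decay 1e-4) under a cyclic learning
rate: within each cycle of c steps the rate descends linearly from α1 to
α2, i.e. α(i) = (1 − t(i))α1 + t(i)α2 with t(i) = (mod(i−1, c) + 1)/c.  At
the end of every cycle the weights are folded into a running average,
w_swa ← (w_swa·n + w)/(n + 1); after k snapshots the average equals their
arithmetic mean (tolerance 1e-12).  Defaults: α1 = 0.1, α2 = 0.05, c = one
epoch of steps, averaging starts after a configurable warm-up and takes 10
snapshots.  Exactly two weight sets are held in memory: the live model and
the average.

Averaging covers weights and biases, not batch-norm running statistics;
those are stale for the averaged point and are rebuilt by one pass over the
training loader with equally weighted batch statistics (`finalize`).  A
model holding an un-finalised average refuses to predict.

## Training defaults and desk scale

Full-scale defaults are the study settings: batch size 32, base learning
rate 0.1, SWA learning rate 0.05, weight decay 1e-4, 100 epochs.  Pixels
are scaled to [0, 1] and standardised per channel with constants from the
training split.

Shipped tests and the acceptance script run a desk-scale configuration
chosen to finish in minutes on one CPU core: 200 generated originals per
class (160 train / 40 held out), crops down-sampled to 50×50, width
multiplier 0.25, 15 epochs with SWA from epoch 6 (10 one-epoch cycles),
and learning rates 0.02/0.01.  The rate scaling follows the problem size:
the 0.1/0.05 schedule belongs to the full-width network trained on ~12 000
augmented images from an ImageNet-initialised start, and at a twentieth of
that scale it does not converge (plain softmax included).  Under the
desk-scale settings the network reaches > 95% training and > 85% held-out
accuracy on the synthetic classes; these thresholds are asserted in the
acceptance suite.

## Evaluation

All metrics derive from a 5×5 integer confusion matrix (rows true, columns
predicted): recall_k = cm[k,k]/rowsum_k, precision_k = cm[k,k]/colsum_k (0
for an empty column), F1 the harmonic mean (0 when P + R = 0), macro
averages unweighted, micro accuracy = trace/total.  The published
test-set confusion matrix ships as a versioned CSV fixture; computing
metrics from it reproduces every published per-class recall, precision and
F1 of the defect network at the tables' printed precision, exactly as
integer fractions before rounding (e.g. rot recall 794/800 = 99.25%, scar
precision 236/273 ≈ 0.86, scar→rot misjudgment 30/280 = 10.7%).

Two cells of that fixture deserve note.  The narrative accounts for only
799 of 800 rain-spot test images; the residual count is assigned to crack,
the unique completion consistent with the published crack precision of
0.93 (125/135).  And the published headline "mean average precision 93.8%"
is not derivable from the published per-class numbers — the macro recall
of the fixture is 90.06% and the micro accuracy 93.56% — so the package
asserts the discrepancy rather than reproducing the headline.

## Known limitations

* The synthetic domain is far easier than photographs; no claim about
  photographic accuracy follows from the shipped runs.
* Timing figures are hardware-bound and out of scope.
* The NumPy engine is single-threaded and desk-scale; it is not intended
  for full-resolution, full-width training runs.
* The guard and the cosine head are the package's own stabilisations of
  the published loss; disabling the guard reproduces the bare formula.
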