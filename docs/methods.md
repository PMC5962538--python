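# Methods

This note records the models, numerical conventions and design choices behind
`conefinder`, and what its synthetic benchmarks do and do not demonstrate.

## Segmentation model

The detector is a per-pixel two-class (background/cone) classifier built from
2D multidimensional LSTM (MDLSTM) layers and 3×3 convolutions:

| layer | in → out channels |
|---|---|
| 3×3 conv, tanh, zero-pad | 1 → 1 |
| MDLSTM layer (4 blocks, u units) | 1 → 4u |
| 3×3 conv, tanh, zero-pad | 4u → 1 |
| MDLSTM layer (4 blocks, u units) | 1 → 4u |
| per-pixel FC, ReLU | 4u → 64 |
| per-pixel FC + softmax | 64 → 2 |

The reference configuration uses u = 32 units. Nothing in the recurrence
depends on the image size, so a network trained on crops applies to arbitrary
h × w images.

**Block recurrence.** One directional block scans the (possibly rotated)
image top-to-bottom, left-to-right. At each pixel, five affine maps of
(input, hidden-above, hidden-left) produce gates i, f1, f2, o (logistic) and
a candidate g (tanh); the cell and hidden states are

    c = i*g + ½ f1*c_up + ½ f2*c_left,     h = o · tanh(c),

with zero vectors for neighbours outside the grid. The ½-convex combination
of predecessor cells is the key stability device: |i*g| ≤ 1 and the forgotten
part is a convex average of already-bounded cells, so |c| ≤ 2 holds uniformly
over arbitrarily long scans (asserted in tests on 200×200 inputs). A plain
additive two-predecessor update grows along diagonals and makes deep 2D scans
untrainable. This update also fixes the block's per-pixel cost at
5uk + 10u² + 6u multiplications (five input and ten recurrent matrix–vector
products plus six element-wise products per unit), i.e. 10592 for (u=32, k=1)
and 30912 for (u=32, k=128) — the accounting behind aggregating each MDLSTM
layer's 4u features to one channel with a convolution before the next layer.

**Directions.** A layer runs four blocks on the 0/90/180/270° rotations of
its input and concatenates the un-rotated results, so each output feature
vector has accumulated context from the whole image. Note the four slabs of a
layer are genuinely different features: even with shared weights and a
4-fold-symmetric input they are 90°-rotations of one another, not copies.

**Implementation.** Forward and reverse passes are NumPy, vectorised over
anti-diagonal wavefronts (all pixels with i + j = t updated at once, batch
folded into the diagonal); reverse-mode gradients are hand-derived and
verified against central finite differences (the scan is smooth; checks pass
at 1e-4 relative in float64). A literal per-pixel recursion
(`block_scan_naive`) is retained purely as a test oracle. Production dtype is
float32; the 1e-6 oracle-equivalence tolerance reflects that. Finite-
difference checks of the *full* network are only meaningful away from ReLU
kinks, where central differences themselves are biased.

## Initialisation and training

- MDLSTM weights ~ N(0, sd 0.25); convolutional filters and (by the same
  rule, since nothing else is specified) fully connected weights
  ~ U(−0.1, 0.1); all biases 0. The Gaussian scale is deliberately small:
  large recurrent weights make gradients explode, very small ones make
  activations vanish. The scale is an `init_params` option.
- Inputs are mean-centred only (variance untouched); during training the
  centring applies to each crop, since the crop is what the network sees.
- Objective: Generalised Dice Loss with w_x = 1/(Σx)², classes background and
  cone; a class absent from the truth gets weight 0 so background-only crops
  stay finite. Batch loss is the mean of per-image losses. GDL is bounded in
  [0, 1] for probabilistic predictions and resists the collapse-to-background
  optimum that plain cross-entropy exhibits at ~1% cone prevalence (both
  properties are tested). An unweighted cross-entropy exists in the code only
  as the baseline for that comparison.
- Optimiser: RMSProp, learning rate 0.001, decay 0.9, momentum 0,
  epsilon 1e-10 (logged in the config).
- Epochs: one epoch is `epoch_size` minibatches of 8 random square crops
  (128 px by default); `epoch_size` defaults to roughly one pass over the
  training pixels. Early stopping monitors the GDL on **full** validation
  images (the loss, not Dice, is the monitored criterion; a hard pixelwise
  segmentation Dice at 0.5 is logged alongside) and stops exactly `patience`
  (default 20) epochs after the best epoch, returning that epoch's weights.

## Centroid recovery

Five ordered steps on the cone-probability channel: Gaussian smoothing,
7×7 local maxima, threshold T, 7-px border rejection, and iterated
single-linkage merging of maxima closer than 8 px (clusters replaced by their
mean until all pairs are ≥ 8 px apart). Conventions chosen where the
procedure is under-determined:

- **σ is a variance** (px²); the filter standard deviation is √σ. This is
  easy to get wrong when porting parameters — stated here prominently.
- A pixel is a local maximum iff its smoothed value is ≥ everything in its
  centred window (clipped at the image edge); equal-valued connected
  plateaus are represented by their topmost-then-leftmost pixel.
- The threshold compares the *smoothed* map, the object in which maxima were
  found. "Below T" rejects strictly; border distance must be ≥ 7.
- All constants (7, 7, 8 px, the 20 px matching cap) are raw pixel units
  regardless of field of view.

Calibration grid-searches σ ∈ {0.5, 1, 2, 4, 8, 16} px² and
T ∈ {0.05, …, 0.95} (step 0.05) for the maximum mean detection Dice on a
validation subset, ties toward smaller σ then smaller T. Three pairs are
kept: healthy-only, disease-only, and joint. Adaptive localisation runs the
joint pair, classifies the image as dense iff strictly more than
0.0011 cones/px were found, and reprocesses with the regime pair.

## Evaluation

Matching tolerance is min(0.75·d, 20) px with d the median nearest-neighbour
spacing of the true cones (20 px when fewer than two exist — in sparse
diseased mosaics d can be arbitrarily large). Candidate pairs within
tolerance are accepted greedily by ascending distance (ties: truth index,
then estimate index), one-to-one; the written-out matching rule is ambiguous
in places, and globally-greedy-by-distance is the standard reading. Detection
Dice is 2TP/(2TP+FP+FN); an image with zero true cones but false positives
is reported as Dice 0 and flagged rather than excluded. Cone-count agreement
uses Bland–Altman statistics: mean difference with a 95% t-interval and
limits of agreement mean ± 1.96·sd, each with the conventional 95% half-width
1.96·sd·√(3/n).

## Synthetic data

The generator emulates split-detection appearance: each cone is a horizontal
intensity dipole (negative Gaussian lobe left of the centroid, positive lobe
right — the shading axis the differential detector produces; the angle is
deliberately not configurable), summed on a low-frequency background (white
noise low-pass filtered at 4× the lobe scale, standing in for slowly varying
retinal texture) plus white noise, rescaled to [0, 1]. Centroids come from a
triangular lattice of pitch `spacing`, perturbed by isotropic Gaussian jitter
of sd `jitter·spacing` **norm-clipped at one sd** — the clipping guarantees
the documented minimum separation spacing·(1 − 2·jitter), which pure Gaussian
jitter cannot — then thinned binomially by `occupancy` and trimmed of points
within one disk radius of the border. Masks dilate centroids to disks of
radius r = max(2, 0.35·spacing), small enough to keep cone borders visible.

Default regimes: healthy mosaics draw spacing 9–12 px, occupancy ≥ 0.92,
contrast 0.8–1.0; disease mosaics spacing 20–26 px, occupancy 0.18–0.34,
lower contrast and more noise. The ranges are chosen so lattice densities
(occupancy/(spacing²·√3/2)) fall strictly on either side of the
0.0011 cones/px dense/sparse cut-off.

What the generator does **not** model: confocal/dark-field channels,
vasculature and other anatomical structure, eye-motion distortion,
eccentricity-dependent cone morphology, merged cone pairs, or grader noise in
the ground truth. Passing the synthetic benchmarks therefore demonstrates
that the architecture, loss, recovery and evaluation machinery are correct
and that the pipeline can recover known mosaics under realistic geometry and
noise — not that clinical-grade accuracy transfers to real AOSLO images,
which are unavailable for redistribution.

## Benchmark scale

The end-to-end benchmark trains an 8-unit network (the 32-unit reference
architecture is identical in code; unit count is a constructor argument) on
40 mosaics of 128×128 px with 64-px crops, 15 steps/epoch, patience 8, at
most 30 epochs, and evaluates on 10 dense + 10 sparse held-out 175×175
mosaics — 175 px being the smallest frame the detector is intended for, and
large enough that the 7-px border exclusion affects < 10% of true cones.
These sizes were chosen as the smallest configuration that cleanly separates
success from failure; they are the package's own experiment defaults, and at
this scale held-out mean detection Dice is ≈ 0.94 (dense) and ≈ 0.99
(sparse), the dense gap being mostly border-zone cones the recovery rules
exclude by construction.

## Known limitations

- Pure-NumPy training is CPU-bound; wall-clock scales roughly linearly in
  pixels × units². The wavefront scan's per-diagonal dispatch overhead
  dominates for very small images.
- The cell-update family is fixed to the ½-convex combination; learned
  mixing weights and peephole connections are out of scope, as are 3D
  MDLSTMs.
- Calibration optimises mean per-image Dice; images with very few cones get
  the same weight as dense ones.
- The dipole appearance model is a stand-in; its realism against clinical
  split-detection data is untested (see above).
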