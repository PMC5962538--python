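# conefinder

Automatic localisation of cone photoreceptor cells in adaptive-optics
scanning-light-ophthalmoscope (AOSLO) **split-detection** images.

Counting cones in AOSLO images is how clinicians track photoreceptor loss in
inherited retinal disease (e.g. Stargardt macular dystrophy) and the effect of
experimental therapies — and it is normally done by hand, one cone at a time.
Automating it is hard precisely in the diseased case: the mosaic loses its
regular quasi-hexagonal packing, contrast drops, and a local image patch is
often ambiguous, so a detector needs context from the *whole* image to decide
whether a dark/bright lobe pair is a cone.

`conefinder` implements a complete detection stack for this problem:

1. **Segmentation network** — a stack of 3×3 convolutions and 2D
   multidimensional LSTM (MDLSTM) layers ending in a per-pixel softmax over
   {background, cone}. An MDLSTM block scans the image in raster order,
   carrying a hidden state `h` and bounded cell state `c` from the pixel above
   and to the left:

   ```
   i, f1, f2, o = σ(Wx + U h_up + V h_left + b),   g = tanh(·)
   c = i*g + ½ f1*c_up + ½ f2*c_left,              h = o · tanh(c)
   ```

   Four rotations of the scan give every pixel context from the entire image.
   The architecture is conv → MDLSTM → conv → MDLSTM → FC → softmax; the
   intermediate convolutions aggregate the 4·u directional features back to
   one channel, cutting a 32-unit block's per-pixel cost from 30912 to 10592
   multiplications. Forward *and* backward passes are written in NumPy with an
   anti-diagonal wavefront vectorisation; a literal per-pixel recursion is
   kept as a test oracle.
2. **Training** — Generalised Dice Loss (inverse-squared class-volume
   weights, robust to the extreme cone/background imbalance), RMSProp
   (lr 0.001, decay 0.9), minibatches of 8 random mean-centred crops, early
   stopping on validation loss with patience 20.
3. **Centroid recovery** — smooth the cone-probability map with a Gaussian of
   variance σ, take 7×7 local maxima, reject below threshold T and within
   7 px of the border, merge maxima closer than 8 px. (σ, T) are calibrated
   by grid search on a validation set, separately for dense (healthy-like)
   and sparse (disease-like) mosaics; at inference a first pass classifies
   the image as dense (> 0.0011 cones/px) or sparse and the matching pair is
   applied.
4. **Evaluation** — one-to-one greedy matching within min(0.75·d, 20) px of
   a true cone (d = median nearest-neighbour spacing), detection Dice
   2TP/(2TP+FP+FN), and Bland–Altman limits of agreement on per-image cone
   counts.
5. **Synthetic data** — clinical AOSLO data are not redistributable, so the
   package ships a generator that renders split-detection-like images (cones
   as dark/bright Gaussian dipoles on textured noise) from jittered, thinned
   hexagonal lattices in healthy-dense and disease-sparse regimes, with exact
   ground-truth centroids and disk masks.

## Worked example

Train a scaled-down (8-unit) network on 40 synthetic 128×128 mosaics,
calibrate recovery on 6 validation images, and score adaptive localisation on
10 held-out dense and 10 sparse 175×175 mosaics:

```python
import numpy as np
import conefinder as cf
from conefinder.network import init_params, forward
from conefinder.training import TrainingConfig, train, preprocess

ss = np.random.SeedSequence(1)
s1, s2, s3, s4 = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
ds_train = cf.generate_dataset(40, 0.5, seed=s1)
ds_val   = cf.generate_dataset(6, 0.5, seed=s2)
ds_test  = cf.generate_dataset(20, 0.5, seed=s3, height=175, width=175)

cfg = TrainingConfig(crop_size=64, batch_size=8, epoch_size=15,
                     patience=8, max_epochs=30, seed=s4)
params, hist = train(ds_train, ds_val, cfg, params=init_params(s4, units=8))

val_maps  = [forward(preprocess(s.image), params)[..., 1] for s in ds_val]
val_truth = [s.centroids for s in ds_val]
pb = cf.calibrate(val_maps, val_truth)                       # joint pair
ph = cf.calibrate(*zip(*[(m, t) for m, t, s in
                         zip(val_maps, val_truth, ds_val)
                         if s.regime == "healthy"]))
ps = cf.calibrate(*zip(*[(m, t) for m, t, s in
                         zip(val_maps, val_truth, ds_val)
                         if s.regime == "disease"]))

scores = {"healthy": [], "disease": []}
for s in ds_test:
    prob = forward(preprocess(s.image), params)[..., 1]
    est = cf.adaptive_localise(prob, pb, ph, ps)
    scores[s.regime].append(cf.dice(cf.match(est, s.centroids)))
for regime, vals in scores.items():
    print(regime, "adaptive mean dice %.4f" % np.mean(vals))
```

On one CPU this takes a few minutes and prints:

```
healthy adaptive mean dice 0.9423
disease adaptive mean dice 0.9955
```

i.e. on held-out synthetic mosaics the pipeline recovers ~94% of dense-mosaic
cones and essentially all sparse-mosaic cones (the residual dense-regime gap
is dominated by true cones inside the 7 px border-exclusion zone, which the
recovery procedure deliberately never reports).

The same flow is available from the shell:

```
conefinder synth --n 40 --healthy-fraction 0.5 --out run/ --seed 1
conefinder train --data run/ --units 8 --seed 1
conefinder pipeline --out run2/ --n 20 --seed 1        # all stages at once
```

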