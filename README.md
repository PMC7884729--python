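# segpick

Semantic-segmentation particle picking for single-particle cryo-EM.

Locating individual macromolecule projections ("particles") in
low-dose, low-contrast electron micrographs is the first and most
labour-intensive step of cryo-EM structure determination. `segpick`
automates it without any manual particle picking: per-pixel training
labels are generated from a handful of micrographs by classical image
enhancement and thresholding, a full-resolution residual network (FRRN)
is trained to classify every pixel as background, protein, crystalline
ice or carbon, and particle coordinates are extracted from the
predicted protein-probability map. Coordinates are written in the EMAN
`.box` and RELION `.star` formats consumed by downstream extraction and
refinement software.

## Method

**Enhancement.** A raw micrograph is rescaled to 8-bit and expanded
into three channels: (1) global histogram equalization followed by an
edge-preserving bilateral filter; (2) a band-pass that keeps only
intensities within a window of the global median (where particles
live); (3) a Gaussian adaptive threshold of channel 2. The stack is
CLAHE-equalized per channel to cancel ice-thickness contrast gradients.

**Automatic labeling.** The enhanced image is intensity-thresholded
(inclusive band, with a polarity switch for dark particles) and
size-filtered (8-connected components within an inclusive area band);
surviving pixels are labeled protein. Ice and carbon are supplied as
regions of interest and take precedence over protein.

**Segmentation network.** The FRRN couples two streams: a
full-resolution residual stream `y` that preserves localization, and a
pooling stream `z` that descends through max-pooled scales to learn
context. The residual unit computes `x_n = x_{n-1} + F(x_{n-1})`; the
full-resolution residual unit computes

    y_n = y_{n-1} + G(y_{n-1}, z_{n-1})      (residual stream)
    z_n = H(y_{n-1}, z_{n-1})                (pooling stream)

and reduces exactly to a residual unit when `H = 0`. The default
assembly uses five pooled scales down and four FRRU stages up, with
index-preserving unpooling. Training uses per-pixel cross-entropy with
inverse-frequency class weights and keeps the epoch with the best
validation mean F1 (`F1 = 2PR/(P+R)`).

**Picking.** The protein-probability plane is thresholded; fragments
within one particle diameter merge into a single particle at their
area-weighted centroid. The threshold is tuned by sweeping a grid and
maximizing particle-level F1 against reference coordinates.

**Evaluation & simulation.** Pixel metrics (precision, recall, F1,
IoU, accuracy, mean IoU) come from the 4-class confusion matrix;
particle metrics from one-to-one greedy centre matching within a pixel
tolerance; PR curves, rectangle-sum average precision `AP = Σ_n (R_n −
R_{n−1}) P_n` and trapezoidal PR-AUC are provided. A scene simulator
renders micrographs with exact ground truth, and Gaussian/Poisson
noise can be injected at a target SNR, defined as the power ratio
`Var(signal)/Var(noise)` in dB.

## Worked example

```python
import numpy as np
import segpick as sp
from segpick.segnet import FRRNConfig, TrainConfig, build_frrn, train, predict
from segpick.pick import PickParams, pick_micrograph
from segpick.evalmetrics import particle_match, f1_score

# 1. simulate three micrographs with exact ground truth
scenes = [sp.make_micrograph(sp.SceneSpec(image_size=(128, 128), n_particles=8,
                                          particle_radius_px=6, seed=s))
          for s in (1, 2, 3)]

# 2. generate training labels automatically (no manual picking)
lp = sp.LabelParams(intensity_low=150, min_area_px=40, max_area_px=2000)
pairs = [(sp.compose_three_channel(mg), sp.generate_label(mg, lp))
         for mg, _, _ in scenes]

# 3. train a miniature FRRN
model = build_frrn(FRRNConfig(n_pooling_stages=2, n_unpooling_stages=2,
                              base_channels=8), seed=0)
model, records = train(model, pairs, TrainConfig(epochs=50, seed=0, crop_size=128))
print(f"best validation mean F1: {max(r.mean_f1 for r in records):.3f}")

# 4. predict and pick
tp = fp = fn = 0
for (mg, _, truth), (tc, _) in zip(scenes, pairs):
    prob = predict(model, tc)
    picked = pick_micrograph(prob, PickParams(particle_radius_px=6, prob_threshold=0.5))
    t, f, n, _ = particle_match(picked, truth, tol_px=6.0)
    tp, fp, fn = tp + t, fp + f, fn + n
precision, recall = tp / (tp + fp), tp / (tp + fn)
print(f"particles: TP={tp} FP={fp} FN={fn}")
print(f"precision={precision:.3f} recall={recall:.3f} F1={f1_score(precision, recall):.3f}")
```

Output (about a minute on one CPU core):

```
best validation mean F1: 0.928
particles: TP=24 FP=0 FN=0
precision=1.000 recall=1.000 F1=1.000
```

The validation F1 is the pixel-level score used for model selection;
the particle-level numbers say that all 24 true particles across the
three micrographs were recovered within one particle radius, with no
false picks.

The same workflow is available from the shell:

```sh
segpick simulate --n-images 6 --out scenes/ --seed 7
segpick label    --in scenes/ --config label.yaml --out masks/
segpick train    --images scenes/ --masks masks/ --config train.yaml --out model.ckpt.npz
segpick predict  --model model.ckpt.npz --in scenes/ --out probmaps/
segpick pick     --probmaps probmaps/ --radius 6 --threshold 0.5 --out coords/
segpick eval     --pred coords/ --truth scenes/ --tol 6 --out report.json
```

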