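# Methods

## Problem setting

Single-particle cryo-EM micrographs are 2D projections of vitrified
macromolecules with very low signal-to-noise ratio, uneven contrast
from variable ice thickness, bright crystalline-ice contamination and
dark carbon-film edges. `segpick` treats particle picking as per-pixel
semantic segmentation over four classes — background, protein, ice,
carbon — followed by coordinate extraction from the protein class. The
design goal is a fully headless pipeline: training labels are produced
by parameterized image processing rather than manual picking, so the
only human input is a handful of threshold values tuned once per
dataset.

## Enhancement stages

All stages operate on 8-bit images and are deterministic. Intermediate
results are re-quantized to 8-bit after each stage so that thresholds
always act in a reproducible integer space.

* `normalize_to_8bit` — linear min/max rescale to [0, 255]; a constant
  image maps to all-128. Invariant under positive affine intensity
  transforms, so camera gain/offset differences are irrelevant.
* `clahe` — contrast-limited adaptive histogram equalization,
  implemented directly: the image is divided into a `tile x tile` grid
  (default 8), each tile's 256-bin histogram is clipped at
  `clip_limit` (default 2.0) times the uniform bin height, the excess
  is redistributed uniformly, and the per-tile CDF mappings are
  bilinearly blended between tile centres. Low clip limits give gentle
  equalization; the default suits most low-contrast micrographs.
* `channel_hist_bilateral` — global histogram equalization followed by
  a bilateral filter (window `bilateral_diameter` = 5 px,
  `sigma_color` = 25 intensity levels, `sigma_space` = 3 px): contrast
  enhancement with edge-preserving noise removal.
* `channel_median_threshold` — keeps pixels within `median_window`
  (default 40 levels) of the global median and zeroes the rest,
  boosting contrast in the intensity range where particles live.
* `channel_adaptive_gaussian` — binarizes at the Gaussian-weighted
  local mean over `adaptive_block` (default 11 px): a pixel fires when
  it exceeds its local mean by more than `adaptive_offset` (default 2
  levels). The offset is *added* to the local mean, so flat regions
  map to 0 instead of firing on rounding noise; this is the only
  convention under which a constant image yields an empty detection
  map for positive offsets, which is what a contaminant-suppressing
  threshold should do.

The three-channel network input stacks stages 1–3 and applies CLAHE to
each channel independently (channels are heterogeneous, so a joint
equalization would be ill-defined).

Two distinct enhancement paths exist deliberately: the *labeling* path
(normalize → Gaussian blur → CLAHE → bilateral → percentile contrast
stretch) and the *network input* path above. They are kept separate
rather than merged because they serve different purposes — the first
feeds thresholding, the second feeds the network.

## Automatic labeling

`generate_label` applies the labeling-path enhancement, then an
inclusive intensity band `[intensity_low, intensity_high]` (after a
polarity flip so dark particles can be selected by a high band), then
an inclusive area band `[min_area_px, max_area_px]` on 8-connected
components. Survivors are protein; user-supplied rectangle/polygon
regions overwrite with ice or carbon (precedence: ice/carbon > protein
> background). The unspecified "contrast enhancement" stage is a linear
stretch saturating 1% tails on each side, exposed as two parameters.
Interactive tuning is replaced by `sweep_thresholds`, which
grid-searches `intensity_low` and `min_area_px` against a small
reference mask and reports the F1-maximizing setting.

## Network

The FRRN couples a full-resolution residual stream (channel width =
`base_channels`) with a pooling stream that descends
`n_pooling_stages` max-pooled scales (channel widths
`base * 2^min(k, 3)`). Each FRRU max-pools the residual stream to the
pooled scale, concatenates it with the pooling stream, applies two
conv3x3–batchnorm–ReLU stages to produce the new pooled features, and
adds a 1x1-projected nearest-neighbour-upsampled copy back into the
residual stream. Zeroing the pooled computation and the projection
makes the FRRU an exact identity residual unit (verified to 1e-6 in
tests). Max-pool argmax indices are reused by the unpooling steps on
the way up, preserving localization.

The default stage counts are five down and four up. The builder always
returns the pooling stream to full resolution: the up path traverses
every scale, attaching FRRU stages to the first `n_unpooling_stages`
of them and using plain adapt-conv + index-preserving unpool for any
remainder. With the 5/4 default this yields exactly five pooled scales
and four up-FRRUs. A 1x1 classifier head over the merged streams
produces logits; softmax gives per-pixel probabilities that sum to 1.

The network and its backpropagation are implemented directly in NumPy
(same-padded im2col convolution, batch normalization with running
statistics, max-pool/unpool, nearest upsampling), with gradients
verified against central finite differences in the test suite.

### Training

* Loss: per-pixel softmax cross-entropy with inverse-frequency class
  weights computed from the training masks — protein pixels are
  typically 2–5% of the image, and unweighted loss collapses to the
  background class.
* Optimizer: Adam, learning rate 1e-3 (exposed in `TrainConfig`).
  Neither is dictated by the pipeline definition; they are the
  standard choice for imbalanced segmentation.
* Data: deterministic seeded 80/20 split (a single image serves as
  both train and validation); one random crop of `crop_size` per image
  per epoch, cropped to the network's divisibility constraint.
* Model selection: per-epoch validation mean F1 over classes present
  in the truth, computed with the package's own pixel metrics; the
  checkpoint with the maximum mean F1 wins, ties going to the earliest
  epoch.
* Reproducibility: given (seed, data, config), the split, crop
  sequence, initialization and updates are all deterministic.

Inference reflect-pads to the divisibility constraint and crops back;
images beyond 512 px are tiled with 32 px overlap and probabilities
averaged in the overlaps.

## Picking

`protein_mask` thresholds P(protein) inclusively. `extract_particles`
drops components below `min_fragment_px` (default 5% of the particle
disk area — speckle rejection), merges components whose centroids are
within `2 * particle_radius_px` (single-link, transitive — the minimal
formalization of "fragments within one particle size belong
together"), and emits one particle per group at the area-weighted
centroid, scored by mean protein probability. `tune_threshold` sweeps
an ascending grid, pooling matched counts over all images, and returns
the F1-argmax threshold with ties to the *higher* value — when two
thresholds pick equally well, the stricter one admits fewer
contaminants.

## Evaluation

Pixel metrics derive from the 4x4 confusion matrix; the 0/0 case maps
to 0 (not NaN) so aggregation stays stable, and mean IoU averages only
over classes present in the truth. Particle matching is one-to-one
greedy by ascending centre distance with tolerance `tol_px`, default
one particle radius — a pick within one radius still yields a usable
extraction box. Average precision uses the rectangle sum
`Σ (R_n − R_{n−1}) P_n` with R_0 = 0; a trapezoidal PR-AUC is provided
separately since published "AUC" figures for pickers are sometimes one
and sometimes the other, and the two agree within 0.05 on reasonably
dense curves.

## Synthetic scenes and noise

`make_micrograph` renders a background at intensity 0.7 with darker
particles (`particle_contrast` fraction below background, default 0.5;
disk, annulus or wobbled-blob shapes), optional bright ice blobs at
0.95, an optional dark carbon band (0.35, 8% of the short edge) along
one border, and an optional linear illumination ramp emulating
variable ice thickness. Particles are placed by rejection sampling
with a 2 px margin; class masks and centre lists are exact by
construction. The generator reproduces the gross geometry and contrast
polarity of real micrographs but none of their physics — no CTF
oscillations, no structured noise, no realistic texture inside
particles — so passing tests demonstrate the pipeline's mechanics, not
its performance on experimental data.

SNR is the power ratio `Var(signal)/Var(noise)` in dB; this is the
convention under which the decibel and linear columns of the
noise-robustness table agree (e.g. −9.5 dB ↔ 0.1122, −16 dB ↔ 0.0251).
One published pair (−5.5 dB ↔ 0.2828) disagrees with the formula
(10^−0.55 = 0.2818) by 4e-4 — presumably a typo; the formula is
implemented. Gaussian noise is additive with variance
`Var(signal)/SNR`; Poisson noise scales the (shifted) image to a mean
photon count at which shot noise (variance = mean) gives the target
SNR, samples counts, and rescales back — calibration verified
empirically to within 0.5 dB on 512x512 images. Values are not clipped
internally; clipping happens only at 8-bit export.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
miniature networks (2 pooled scales, 8 base channels, ~30k
parameters), 64–256 px scenes, 50–200 epochs. These sizes were chosen
so that each check isolates one mechanism (capacity, calibration,
monotonicity) rather than benchmarking throughput; production use on
4k micrographs is supported through the same API via tiled inference
and random-crop training.

## Known limitations

* No CTF or defocus modelling anywhere; the simulator's contrast model
  is piecewise-constant.
* The labeling tool cannot discover ice/carbon automatically; it takes
  regions of interest (the network, once trained, does predict those
  classes on its own).
* Training is CPU-bound NumPy; full-scale training on hundreds of 4k
  micrographs would need hours, not minutes.
* Coordinates are 0-based pixels with x = column, y = row, origin
  top-left; `.star` files are written 0-based (the dialect's base is
  not standardized — convert downstream if a 1-based consumer
  complains).
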