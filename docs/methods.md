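# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limitations of `aqua-ae`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Frames from aquarium monitoring video are low-contrast: subject contours
blend into a murky, unevenly lit background, so intensity gradients are
weak. The package addresses two operational needs: compressing such frames
into small latent codes for archival, and deriving observation images in
which the subjects stand out. Both are served by symmetric autoencoders —
an encoder compresses a frame to a latent code, a mirrored decoder
reconstructs it — trained self-supervised on the frames themselves.

## Autoencoder architectures

Architectures are declared as dash-separated stage widths.

**MLP.** Input flattened to `side²·3`; dense stages with ReLU down to the
latent width (the last stage); mirrored dense stages back up; sigmoid
output dense of size `side²·3`. Every dense layer has a bias, so its
parameter count is `n_in·n_out + n_out`. The full-scale baseline
`256-128-64` at side 256 has per-layer counts 50,331,904 / 32,896 / 8,256 /
8,320 / 33,024 / 50,528,256 (total 100,942,656).

**CNN.** Per encoder stage: `3×3` same-padding convolution (ReLU, bias)
followed by `2×2` max pooling; the latent is the final pooled tensor, of
shape `(side/2^k, side/2^k, last_filters)` for `k` stages. The decoder
mirrors the stages in reverse with stride-1 `3×3` transposed convolutions
(each followed by `2×` nearest-neighbor up-sampling), and the output head
is a `3×3` convolution to 3 channels with sigmoid. A convolution holds
`9·c_in·c_out + c_out` parameters; pooling and up-sampling hold none. The
output head is deliberately a convolution rather than a per-pixel dense
map: for a 256-filter final stage it holds `9·256·3 + 3 = 6,915`
parameters, which matches the published baseline account of this
architecture family, whereas a per-pixel dense head would hold only 771.

At stride 1 with same padding, a transposed convolution is exactly a
convolution with the spatially flipped kernel; it is implemented that way
and kept as a distinct layer type so decoder summaries mirror the encoder.

**Parameter accounting is structural.** Counts and layer tables are
computed from shapes alone, so a hundred-million-parameter MLP can be
audited in milliseconds; weights are allocated lazily by
`initialize(seed)` (uniform in `±1/√fan_in`, PCG64-seeded).

## Training

Input = target; loss is binary cross entropy for MLPs and per-pixel mean
squared error for CNNs (per-pixel means keep loss magnitudes independent
of image area). Optimizer: Adam with step size 0.001 and moment decays
0.9/0.999 (standard values; only the method and these three constants are
fixed, everything else is exposed in `TrainConfig`). Defaults follow the
full-scale study settings: 512 epochs, batch size 8, seeded 80/20
train/validation split. "Convergence" is operationalized as early
stopping: training stops when the validation loss has not improved for
`patience` epochs (default 32) and the best-epoch weights are restored.
Under a fixed seed and single-threaded BLAS, runs are reproducible
bit-for-bit: initialization, the split, and every epoch's batch order all
derive from the configured seed.

## Benchmark metrics

`standardize` is global min-max rescaling; a constant input maps to zeros
(constant difference images are legitimate, e.g. identical frames, so this
degenerate case must not raise). `image_diff` standardizes the
*subtraction* `X − Y`, guaranteeing output in [0, 1]. `color_diff` is the
mean over pixels of the squared per-channel difference — mean, not sum, so
the value does not scale with image area; a `reduction="sum"` switch is
kept for auditability. `benchmark` is the square root of the summed
per-channel differences: symmetric, zero iff the images agree, bounded by
√3 for unit-range inputs, and √3·δ for a uniform offset δ.

Histogram statistics pool all per-channel count vectors (256 bins over
[0, 1] by default, the 8-bit convention) into one sequence and report its
min, max, population standard deviation (divide by N), scale = max − min,
and COV = std/mean. Pooling across the image set is the default; per-image
statistics remain available by passing single histograms.

## Difference-image denoising

A model trained on the background reconstructs a fish scene without the
fish; `DIFF = image_diff(frame, reconstruction)` then carries the
subjects, and `DIFF2 = sobel(DIFF)` sharpens their contours. The Sobel
step collapses RGB to luminance (Rec. 601 weights 0.299/0.587/0.114),
applies the horizontal and vertical 3×3 Sobel operators with
replicate-edge borders (a constant frame must have zero gradient
everywhere; zero padding would manufacture frame-boundary edges), takes
the magnitude `√(gx² + gy²)`, and min-max standardizes. The single channel
is replicated to RGB for display.

An alternative path retrains a second (MLP) autoencoder on the DIFF images
and Sobel-treats *its reconstruction* (`observe(..., diff_model=...)`).
On the synthetic fixtures this path performs worse: an MLP retrained on
DIFFs reproduces only static background structure and smooths away the
position-varying subjects, so the direct Sobel-of-DIFF path is the default
and the one used in the salience experiment.

## Synthetic scenes

The generator emulates the documented properties of compartment footage:
a dim blue-green base color; a horizontal illumination ramp, brightest at
column 0 (additive, zero-mean, amplitude 0.4 × `gradient_strength`);
low-alpha rectangles and ellipses standing in for fixtures and
reflections (`clutter_density` scales their count, up to 12); additive
iid Gaussian pixel noise (`noise_sigma`); and fusiform fish — a body
ellipse plus a tail ellipse, rotated — offset from the local background by
`contrast_delta` with a small per-channel tint. Boxes are the exact
silhouette extent, so every foreground pixel lies inside its box. Fish are
placed without box overlap (bounded retries, then an explicit placement
error). Scenes are bit-deterministic functions of their parameters
(PCG64, fixed drawing order), and dataset items use per-scene seeds
`seed + index` so any subset is independently reproducible.

Defaults, chosen once as a plausible emulation of murky footage:
`contrast_delta = 0.1` (a genuinely low-contrast subject; the value is a
calibration choice, not a measured property), `noise_sigma = 0.05`,
`gradient_strength = 0.3`, `clutter_density = 0.1`, 3 fish, 64×64 at test
scale. What the generator does **not** emulate: structured sensor/codec
noise (its noise is iid Gaussian), water turbidity as depth-dependent
scattering, fish texture and kinematics, temporal correlation between
frames. Tests passing on these scenes therefore demonstrate the machinery
(shapes, determinism, descent, relative orderings), not performance on
real footage.

## Preprocessing

Order: quality filter → enhancement → square padding → augmentation →
resize. Padding precedes augmentation because rotation assumes a square
frame. Squaring embeds a crop centered (offset `floor((S − dim)/2)`) in a
zero-filled square of side `max(H, W)`, preserving aspect ratio exactly.
The quality filter drops images whose maximum per-channel standard
deviation is below τ (default 0.02) — variance as the simplest observable
proxy for "too flat to train on". Enhancement applies brightness
(multiplicative, default 2), contrast (scaling around the per-channel
mean, default 0.6 — the factors are taken at face value), then an
unnormalized 3×3 kernel (all neighbors −1; center 11 by default, sum 3,
which intentionally amplifies and relies on clipping; center 9 is the
sum-1 sharpening variant), clipping to [0, 1] after each step. The kernel
is applied as a correlation with zero-padded borders. Augmentation yields
`(1 + #shifts) × (360/step)` images: all rotations (default every 45°;
right-angle rotations are exact index permutations, others bilinear with
zero fill) of the original and of each shifted variant. Resize is
center-aligned bilinear interpolation.

## Latent storage

One byte per latent element: linear min-max quantization to uint8
(round half up) with the observed `(qmin, qmax)` kept in the record, so
dequantization is exact to half a step, `0.5/255·(qmax − qmin)`. A
`(32, 32, 64)` latent is exactly 64 KB raw; Base64 inflates by 4/3 to
87,384 characters ≈ 85.3 KB, under the 86 KB ceiling (KB = 1024 bytes —
the only reading consistent with both figures). Records are JSON documents
under `{date}/{hour}/{source}-{sequence}` keys on a filesystem root; the
put/get/list-by-prefix interface is the contract a document database would
satisfy, and a server-backed implementation can be swapped in behind it.
A BLOB/CLOB relational path is documented here as an alternative but not
implemented: many relational stores cap large objects at 64 KB, which the
Base64 form exceeds.

## Desk-scale experiments (`aqua_ae.experiments`)

The reference experiments run on 64×64 scenes at the default conditions —
sizes chosen so the whole suite runs in minutes on one CPU:

* **Descent** — a `32-16` CNN trained on 200 scenes for 12 epochs; reports
  best/epoch-1 validation-loss ratio (halving is the expected behavior).
* **Trained vs untrained** — 10 seeds; 3 epochs of training on the 80%
  split vs a freshly initialized model, compared by mean reconstruction
  benchmark on the 20% split.
* **Salience** — a `32-16` CNN trained 6 epochs on 100 background-only
  frames, then observed on 20 fish scenes; reports the mean DIFF2
  intensity ratio inside vs outside the ground-truth boxes.

On the salience experiment: the ratio is reliably above 1 (the subjects
are brighter in DIFF2 than the background), but iid pixel noise bounds how
large it can get — noise contributes Sobel response uniformly across the
frame, while the flat fish interiors contribute none (only the silhouette
edge band does). Even substituting the exact noise-free background for
the reconstruction leaves the ratio near 1.2–1.4 at the default noise
level; markedly higher ratios would require milder noise than the
committed conditions. This is a property of edge-based salience under iid
noise, not of the model.

## Known limitations

* Pure-NumPy training is single-core and unsuited to full-scale 256×256
  runs with hundreds of epochs; the package targets desk-scale experiments
  and auditability, not throughput.
* BCE/MSE losses measure per-pixel fidelity only; no perceptual metrics.
* The synthetic scenes omit temporal structure, so nothing here speaks to
  video-rate or tracking behavior.
* `split_dataset` splits at the image level; augmented variants of one
  source image can land on both sides of the split if augmentation is done
  first.
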