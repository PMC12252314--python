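# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests demonstrate.

## The measurement problem

Torsion — rotation of the eye about the line of sight — leaves the pupil
contour unchanged, so it must be read off the iris texture. The package
treats torsion estimation as self-supervised rotation regression: given a
64×64 iris crop, predict the angle by which its texture is rotated
relative to a reference pose. Rotated training inputs are manufactured
from unrotated crops, so no manual angle annotation is needed; the pose of
the unrotated training crops *defines* the zero of the torsion scale. At
inference the estimator maps each non-overlapping window of 3 consecutive
crops (0.1 s of 30 fps video) to one angle, producing a 10 Hz torsion
series.

## Torsion Transformer

**Inputs.** 3-frame stacks of 64×64 single-channel crops, unit intensity
scale. A published description of this architecture is ambiguous about
whether "64 × 64 × 3" means RGB or the frame stack; infrared VNG frames
are single-channel, so the 3 is resolved as the temporal stack.

**Skip blocks.** Each of the three frame positions has its own block:
3×3 convolutions of 16 → 64 → 1 channels (ReLU), concatenation with the
input frame (64×64×2), then 16 → 31 channels. The three 31-channel
outputs are merged by element-wise sum — the merge operation is not
pinned down by the source material; the sum is permutation-simple and
shape-preserving.

**Anchor bank.** 31 learnable 64×64 matrices, one per grid angle
(−15°…+15°, 1° steps). An anchor acts on a 64×64 feature slice by
right matrix multiplication, i.e. a learned global mixing of columns
(configurable to left multiplication). Anchors are initialised at the
identity plus 0.01 Gaussian noise so every branch starts as a
pass-through, which stabilises early training.

**Decoder.** Per training sample, 3 of the 31 anchor branches are
retained (block-level dropout): the anchor nearest the target angle plus
2 drawn uniformly without replacement — the supervised target is then
always reachable while the redundancy-reduction intent of branch dropout
is preserved. Each retained product passes a conv block of 16 → 64 → 1
filters; the 3 maps stack depth-wise in anchor-index order and are
compared with the rotated 3-frame stack (frame order preserved) by MSE
over all pixels, fill regions included. The anchor conv block is shared
across branches by default (`per_anchor_blocks=True` gives each branch
its own); the per-branch specialisation already lives in the anchor
matrices, and sharing keeps the parameter count and step time at desk
scale.

**Finder.** The stack is lifted to 31 channels by one 3×3 convolution;
channel *a* is mixed by the *shared* anchor matrix *a* (this is the only
coupling between the heads apart from the joint loss); convolutions
condense to 3 → 12 channels, a 2×2 max pool halves the map, a final
convolution gives 32×32×4, and a two-layer head (1024 → 31) produces
logits. The prediction is the softmax expectation over the grid angles —
continuous, differentiable, and bounded to [−15°, +15°] by construction.
Training uses the Huber loss (δ = 1°), which is quadratic for errors
below 1° and linear beyond, in place of categorical cross-entropy over
the 31 bins; a config flag can add a cross-entropy auxiliary term
(default off).

**Training input of the Finder.** The Finder is fed the *rotated* stack
with the applied rotation as target. Feeding the unrotated stack (as a
literal reading of the source architecture would suggest) is not
learnable — the pretext angle is drawn independently of the unrotated
content — and would also break the rotation-equivariance property that
the whole measurement rests on.

**Joint objective.** Total loss = decoder MSE + finder Huber, unweighted;
both gradients flow into the shared anchors. Optimiser: Adam, learning
rate 1e-3 (the optimiser for this stage is not pinned by the source;
Adam is the package default), batch 32 (64 in the reduced experiments).
Weight init: seeded uniform with fan-in scaling. All convolutions are
3×3, stride 1, zero-padded; pooling is max, window 2.

**Reduced configuration.** `TorsionNetConfig.small()` shrinks the free
channel counts (skip 4/8, post-concat 4/31, anchor block 4/8/1, dense
256) while keeping everything architectural — 31 anchors, 64×64 maps,
3-frame stacks — intact. The benchmark experiment trains it on ~2,000
synthetic rotation samples from 6 scenes for 3 epochs; on one CPU this
takes a few minutes and reaches a held-out MAE around 0.3°, against a
7.5° predict-zero baseline. The sizes were chosen so the whole benchmark
runs comfortably on a single CPU; accuracy saturates well before the
capacity limit of the reduced model on this data.

## Nystagmus detector

Windows of `window_size` consecutive torsion samples (default 3 = 0.3 s
at 10 Hz, the best-performing length in the clinical study this package
models) are classified by a nine-layer 1D-CNN: three blocks of three
kernel-3 convolutions with 32/64/128 channels, max pooling (ceil mode)
after blocks 1–2, global average pooling after block 3, dense 1024 → 2,
softmax. The positive-class probability is thresholded at 0.5, boundary
inclusive. Channel counts, kernel size and strides are package defaults
(not pinned by the source); the two-neuron head with softmax is
decision-equivalent to a single sigmoid unit on the logit difference.

Training: binary cross-entropy, Adam, early stopping once the loss has
failed to improve on its *running best* by ≥5% for 3 consecutive epochs.
The train/validation split is by source series, never by window, to
prevent leakage of waveform identity. Windows are non-overlapping in
training and evaluation; overlap is configurable for deployment-style
scanning.

## Synthetic data

**Eye frames.** 224×224 8-bit frames: constant sclera (200), dark pupil
disk (25), iris annulus with base intensity 120 modulated by (a) 6 seeded
angular harmonics of random order 2–12, phase and amplitude (total span
38 intensity units) under a radial window, and (b) a seeded polar speckle
field (20 radial × 180 angular bins, SD 16) interpolated with angular
wraparound. Harmonic orders ≤ 12 keep the angular autocorrelation
single-peaked over ±15°, so rotational registration has a unique optimum
— a purely concentric iris would make torsion unobservable. Region
boundaries get a 1-pixel soft transition (optical blur); rendering at
angle θ evaluates the texture at displaced polar angle, so identical
(scene, θ) calls are bit-identical. An optional eyelid occluder masks the
top fraction of the annulus and is excluded from the oracle mask.
Additive Gaussian pixel noise (default SD 2 in the experiments) is seeded
from (texture seed, θ).

**Sign convention.** Positive angle rotates displayed content
counterclockwise (origin top-left, x right, y down). Renderer, box
rotation and waveforms share it; only consistency is observable.

**Waveforms.** Nystagmus: sawtooth beats — a linear slow phase covering
`amplitude` degrees peak-to-peak over 90% of the beat period, then a fast
reset — with amplitude drawn from 5–15° and beat frequency from 1–3 Hz
per series, plus 0.3° Gaussian noise; sampled so the grid straddles the
reset rather than landing on the beat boundary. Normal: 1° sinusoidal
drift at 0.2 Hz plus the same noise. Angles clip to ±15°. The pathologic
amplitude range is clinically grounded; the beat-frequency and
slow/fast-ratio defaults are plausible values, configurable, and not
claimed to be calibrated to any cohort.

**What the simulator does not emulate.** Pupil dilation, eyelash and
reflection artefacts, defocus, gaze-direction changes, elliptical pupils,
head motion, and the intra-class variability of real iris texture.
Passing tests therefore demonstrate that the pipeline measures what it
claims *when segmentation is correct and the texture carries the angle* —
they do not establish clinical performance.

## Preprocessing

CLAHE on the luminance channel (LAB for RGB input; grayscale is used
directly); the clip limit is scikit-image's normalised parameter, default
0.02 on an 8×8 tile grid. Segmentation is a strategy interface — oracle
(ground truth; synthetic pipeline), classical (multi-Otsu mid-band +
largest connected component + annulus fit), external (mask files) — a
pretrained segmentation network is deliberately out of scope and would
slot in as a fourth strategy. Frames that fail segmentation are dropped
and logged, never imputed: bad segmentations are known to corrupt the
angle estimate more than a missing sample does. The crop takes the mask's
minimum enclosing circle, pads where the square leaves the frame,
rescales so the circle diameter is exactly 64 px (bilinear, smoothed
before downscale to avoid aliasing the speckle), and normalises intensity
to [0, 1]. Frame size 224×224 is the default working resolution.
Rotation uses bilinear interpolation with zero fill; losses are computed
over the full 64×64 frame including fill.

## Numerical choices

- All network arithmetic is float32; the autodiff engine preserves
  float64 when tests build float64 graphs for finite-difference checks.
- Convolutions run through JIT-compiled direct kernels (two loop orders,
  chosen by channel shape); `fastmath` reassociation makes them fast and
  they remain run-to-run deterministic. Results agree with the
  matrix-multiply formulation to ~1e-4 (float32).
- Training is exactly reproducible per seed: data generation, splits,
  shuffling, anchor draws and weight init all derive from explicit seeds
  (`numpy` `SeedSequence`); there is no global random state. Outputs for
  identical samples within one batch agree only to ~1e-6 (BLAS blocking),
  which is why "identical input ⇒ identical output" tests use a 1e-3 °
  tolerance rather than bit equality.
- Softmax is computed with max subtraction; BCE clips probabilities at
  1e-7; a non-finite training loss aborts with a diagnostic rather than
  continuing.
- Undefined metrics (zero denominators) are reported as explicit `None`,
  never as 0.
- The minimum enclosing circle is computed exactly (Welzl, via shapely)
  on the mask boundary pixels.

## Known limitations

- The zero of the torsion scale is defined by the training pose; absolute
  torsion on a real recording would require a reference segment (e.g.
  gaze-neutral fixation) to anchor it.
- The reduced-scale benchmark trains and evaluates on the same 6 synthetic
  scenes (disjoint samples); it measures angle recovery, not
  generalisation across irises.
- The classical segmentation strategy assumes the three-way intensity
  ordering pupil < iris < sclera and a roughly annular iris; it is a
  fallback, not a clinical segmenter.
- Decoder reconstruction quality is reported for completeness; at reduced
  scale the decoder is an auxiliary task and its RMSE/SSIM are not tuned.
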