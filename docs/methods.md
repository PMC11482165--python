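# Methods

This note documents the models, algorithms and design choices behind the
package: the sliding-window L1 speckle-decorrelation baseline, the
SE-block U-Net that regresses high-SNR decorrelation maps from a few
co-located B-scans, the dynamic-speckle phantom that stands in for
in-vivo data, and the evaluation stack.

## Speckle decorrelation

OCT angiography contrasts moving blood against static tissue through
temporal speckle change. At each slow-axis location a block of N
co-located B-scans is acquired; the decorrelation statistic is

    D(z, x) = (1 / (N−1)) · Σ_{t=1}^{N−1} |I_t(z,x) − I_{t+1}(z,x)|

— the mean absolute intensity difference over the N−1 *adjacent* frame
pairs — followed by a uniform 6 × 6 (x × z) spatial box average. The
ground-truth *label* is the same statistic computed from all 10 frames
of a block, the best estimate available from one acquisition, and it is
the regression target for the networks.

Conventions the statistic leaves open, fixed here:

* **Pair scheme.** "Sequential pairs" is read as the N−1 adjacent pairs,
  not all N(N−1)/2 pairs; at N = 2 this degenerates to the single pair.
* **Window anchoring.** A 6 × 6 box has no centre pixel; output pixel
  (z, x) averages rows z−2…z+3 and columns x−2…x+3. The brute-force
  oracle in the tests hard-codes the same convention.
* **Edge policy.** Borders use mirror (reflect) padding by default so
  the map keeps the image size; `shrink-window` (renormalise by the
  in-bounds window area) and `crop` (valid region only) are selectable.
* **Intensity scale.** The statistic is positively homogeneous
  (scaling intensities by k scales D by k) and is computed on whatever
  scale the input volume stores (linear for the phantom); the scale is
  carried in volume metadata rather than guessed.
* **Label windowing.** The 10-frame label uses the same 6 × 6 window as
  the baseline.

### Estimator noise vs N

The N−1 adjacent |difference| terms share frames, so they are
1-dependent: for additive noise, corr(|d_t|, |d_{t+1}|) ≈ 0.22. The
std ratio of the N = 2 to the N = 10 estimate is therefore

    sqrt(81 / (9 + 16·ρ₁)) ≈ 2.5,

not the sqrt(9/1) = 3 that independent terms would give. The test suite
asserts the monotone variance reduction and checks the measured ratio
against both values; the scaling is √N-*type* (noise falls roughly as
1/√(N−1)) without matching the independent-pair constant exactly.

## Dynamic-speckle phantom

No public dataset accompanies the reconstruction task, so every stage
is exercised on a synthetic C-scan with known ground truth. Each pixel
carries a circular complex Gaussian field evolving as a stationary
AR(1) process,

    E_{t+1} = ρ·E_t + sqrt(1 − ρ²)·ε_t,   ε_t ~ CN(0, 1),

whose intensity |E_t|² is unit-mean exponential (fully developed
speckle). The temporal field correlation ρ is the ground-truth
parameter: ρ = 0.95 in static dermis, ρ = 0.05–0.3 inside vessel disks
(vasodilated flow). Intensity is scaled by an exponential depth-decay
A(z) = exp(−μ·(z − z_surf)) below the tissue surface and is zero above
it, plus an additive half-normal noise floor — emulating the
depth-dependent SNR loss of skin OCT. Useful closed forms: at ρ = 0,
A = 1, no noise, I_t are i.i.d. unit-mean exponentials and
E|I_t − I_{t+1}| = 1 (Laplace); at ρ = 1 with no noise the block is
static and D ≡ 0. A Monte-Carlo oracle (`expected_l1_map`) computes
E|I_t − I_{t+1}| per pixel with its standard error for arbitrary
(ρ, depth, noise) and anchors the decorrelation and training tests.

Simplifications, and what they imply about the tests:

* **Pixels are spatially independent** (no speckle grain) by default;
  an optional complex-field blur exists but is off. This makes the
  variance analysis clean but means the phantom does not test
  resolution-limited speckle statistics.
* **AR(1) is not a flow model.** ρ maps monotonically to flow speed but
  carries no physics (no fringe washout, no projection artifacts); the
  phantom validates reconstruction, not haemodynamics.
* **Vessels are disks, constant along Y** (optional sinusoidal
  meander), so en-face projections show straight or wavy tracks; no
  branching morphology.
* **No bulk motion.** The paper's scans are registered upstream; the
  phantom is registered by construction, so motion robustness is
  untested.

### Standing study conditions (`octa.experiments`)

The reference experiments run on a "heated" (vasodilated) condition:
64 × 64 px B-scans, 10 frames, 20 slow-axis locations per volume, nine
vessels of radius 4–7 px with ρ = 0.05–0.3 in the first ~50 px below
the surface, static ρ = 0.95, attenuation 0.03/px, noise floor 0.05.
Vessel density and the attenuation gradient matter: they give the
10-frame label genuine spatial structure. A sparse phantom yields a
noise-dominated label, and against such a label the windowed baseline
is unbeatable in principle — it shares its L1 noise terms *and* its
speckle brightness texture with the label (frames 1…N are a subset of
frames 1…10), an advantage any independent predictor lacks. Structure-
rich labels are precisely the regime the in-vivo comparison lives in.

## Network architecture

Both variants are one implementation: a 2-D U-Net whose input channels
are the N co-located B-scans and whose single output channel is the
decorrelation map.

* Encoder: `depth` double-convolution blocks (3 × 3, zero-padded, norm,
  ReLU, twice) with 2 × 2 max pooling; features start at
  `base_features` and double per level; a bottleneck double-conv at the
  bottom. Decoder: nearest ×2 upsampling, concatenation with the
  matching encoder skip, double-conv; final 1 × 1 convolution. Output
  is linear — targets are normalized decorrelation under MSE, and a
  saturating output nonlinearity is unnecessary.
* The SE variant inserts a squeeze-and-excitation block (global average
  pool → C → C/r → C bottleneck MLP → logistic gates, gates strictly in
  (0, 1)) after every double-conv block in encoder, bottleneck and
  decoder, reduction r = 16 at full scale, r = 4 in the small variant.
  The parameter overhead per block is 2C²/r + C/r + C, checked in the
  tests against a closed form.
* Full-scale defaults (depth 4, base 64) follow the conventional U-Net
  topology; the desk-scale variant used in tests and experiments is
  depth 2, base 12–32.

**Normalization layers.** Instance normalization (per-sample,
per-channel spatial moments, affine) is the default. Batch
normalization is implemented and selectable (`ModelConfig.norm =
"batch"`), but with batch sizes of 2–4 and heavy-tailed exponential
speckle activations its eval-mode running statistics do not represent
any actual batch: eval-mode error on the *training* set was several
times the train-mode loss and depended on the shuffle order, and
re-estimating the statistics over the full training set ("precise BN")
did not close the gap because the network learns to rely on per-batch
normalization. Instance norm makes train- and eval-mode outputs
identical by construction, which the best-checkpoint selection and the
tiled prediction path both need.

The whole stack — convolution via sliding windows, norm layers,
pooling, upsampling, SE blocks, Adam, the plateau scheduler — is plain
float64 NumPy with hand-written reverse-mode gradients; every backward
pass is pinned against central-difference numerical gradients in the
test suite, and runs are bit-reproducible on one CPU given a seed.

## Training

Instance–label pairs: instances are the first N frames of a block,
min-max normalized per block with one shared min/max so inter-frame
differences (the signal) survive; labels are the 10-frame maps, min-max
normalized jointly per volume. Patches are cut in the X–Z plane; at
full scale two 512 × 512 patches with a 160 px x-overlap per B-scan
(offsets {0, 352} on a 1000 px scan — the stated overlap is honoured
even though it leaves columns ≥ 864 unused; `full_cover` moves the
second patch to the right edge instead). The patch depth window is
anchored at the detected tissue surface. Splits are assigned per
volume; provenance tags on every pair make the exclusivity checkable.

Optimisation: Adam (weight decay 1e-5, classic L2-style), MSE loss,
batch size 2, 20 epochs, learning rate 5e-4 at full scale; the
validation loss is monitored every epoch and the learning rate is cut
10× after two consecutive epochs without a relative improvement of at
least 1e-4 (patience and factor fixed, the threshold is this package's
choice). The checkpoint with the lowest validation loss is returned —
the selection rule is a package choice, as is aborting on non-finite
loss rather than clipping gradients. The desk-scale experiments use
lr 1e-3–2e-3, batch 2–4 and 20–22 epochs; with ~100× fewer pixels per
patch than the full-scale recipe, the larger step size compensates for
the smaller per-step gradient information.

**Prediction geometry.** A network trained on patches is applied to
full B-scans by tiling with the *training* patch geometry — full-width
tiles anchored at the patch depth window, overlapping outputs averaged,
optionally cropping a border margin distorted by zero padding. Full-
frame inference on a differently sized image shifts the spatial-content
statistics entering the normalization layers and SE gates and degrades
the output badly; rows outside the trained depth window are zero-filled
rather than extrapolated. The reference experiments sidestep seams
entirely by making the patch span the full image width.

## Evaluation

* **PSNR (normalized MSE).** Label and prediction are min-max scaled to
  [0, 255] *independently*; PSNR = 10·log₁₀(255²/MSE) on those images.
  This makes the score invariant to positive-affine rescaling of either
  argument — needed because decorrelation magnitude varies with N. The
  MSE = 0 case (affine-related inputs) returns a flagged +∞, detected
  with a tolerance of 1e-18·255² to absorb float rounding.
* **SSIM.** Standard form, k₁ = 0.01, k₂ = 0.03, L = 255, 11 × 11
  Gaussian window; σ = 1.5 (the conventional value; the window size is
  given, the σ is not). Per-window values are averaged over windows
  fully inside the image. Cross-checked against scikit-image to 1e-6.
* **ROI.** Metrics are computed from the detected skin surface down
  150 px at full scale (28 px at phantom scale) — the high-signal band;
  deeper rows are attenuation-dominated. Surface detection thresholds
  the depth-smoothed row-mean intensity at a configurable fraction
  (default 0.3) of its maximum and is validated against the phantom's
  known surface to ±2 px.
* **En-face MIP.** Maximum over an inclusive depth band measured from
  the surface, per (y, x) — the standard vascular rendering; per-band
  MSE between grayscale-normalized label and prediction MIPs
  supplements the per-B-scan metrics.

Degenerate predictions (constant maps, e.g. from an untrained network
clipped at zero) are reported as NaN rows rather than crashing the
report.

## Reference experiments and their scale

`octa.experiments` fixes four deterministic experiments (sizes chosen
so the full suite fits in CPU minutes):

1. **Estimator-noise scaling** — 200 re-imagings of a frozen speckle
   pattern with additive half-normal noise; per-pixel std of the
   windowed estimate at N = 2, 4, 10.
2. **Loss vs channels** — 3 seeds × {SE-U-Net at N = 2 and N = 6};
   8 training + 1 validation phantoms of 10 locations, depth-2/base-8
   model, 16 epochs; reported as mean final training loss per N. The
   experiment deliberately sits in the data-rich regime (small model,
   many pairs): once a model can memorize its training set, final
   training loss measures memorization speed — at which the simpler
   N = 2 mapping wins — rather than the information content of the
   input, which is what the comparison is about.
3. **SE stabilisation** — 3 seeds × {SE, plain} U-Nets at N = 2 on
   identical data and seeds; 6 training + 1 validation phantoms,
   depth-2/base-12 models, 16 epochs. Reported: the std of successive
   validation-loss differences after epoch 10 (late-epoch jitter) per
   variant. This uses the larger model because the oscillation the SE
   gates damp only appears when the network has capacity to chase the
   validation set.
4. **Crossover** — 12 training + 1 validation + 1 held-out test
   phantom (20 locations each), depth-2/base-32 SE-U-Net, N = 2,
   22 epochs; PSNR/SSIM against the 10-frame label in the 28-px ROI,
   compared with the windowed baseline at N = 2, 3, 4.

Passing these at phantom scale shows the pipeline reproduces the
*qualitative* structure of the full-scale results — loss ordering in N,
SE smoothing, and the N = 2 network reaching the N = 4 baseline — not
the in-vivo numbers, which require the original dataset and GPU-scale
training.

## Known limitations

* The NumPy networks are CPU-bound and orders of magnitude slower than
  a GPU framework; the full-scale architecture (depth 4, base 64,
  512 × 512 patches) is configurable but not practical to train here.
* The phantom's independence and AR(1) assumptions are idealisations;
  none of the tests certify behaviour under bulk motion, spatially
  correlated speckle, or real tissue heterogeneity.
* Batch-norm mode is correct (gradient-checked) but known to interact
  poorly with tiny batches on this data; it exists for completeness.
* `ssim` aggregates per-window values over the whole ROI; if the
  intended aggregation were per-512-patch means of per-window means,
  values would differ slightly on inhomogeneous images.
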