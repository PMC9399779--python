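# Methods

## The model

`scalestack` implements multi-resolution stacked generalization for
multi-label classification of grayscale images. One base classifier is
trained per square input resolution ("scale") from an ordered pyramid of
the same image; a second-level stacking layer then learns, for every
finding `f` (label) independently, a convex combination over scales:

    w_fs = exp(V_fs) / Σ_s' exp(V_fs'),      Σ_s w_fs = 1,
    PL_f(x_i) = Σ_s w_fs · σ(z_fs(x_i)),

where `z_fs(x_i)` is the scale-`s` classifier's logit for finding `f` on
image `x_i` and `σ` is the logistic function. `V = 0` gives uniform
weights, so the fit starts from plain model averaging. The raw matrix `V`
(findings × scales) is fit on *validation* logits by minibatch gradient
descent on binary cross-entropy — 100 epochs, initial learning rate 0.1,
exponentially decaying — and the weights `W` are always re-derived from `V`
by row-wise softmax, never stored separately. Each finding's gradient is
averaged over the batch's images only, so the number of findings does not
dilute the step size. Epochs are minibatch passes (batch size 8 by
default): full-batch descent at learning rate 0.1 cannot travel far enough
in 100 epochs to concentrate a weight row when the evidence demands it,
while small shuffled batches reach the cross-entropy optimum of the
validation set almost exactly. The decay factor defaults to 0.995 per
epoch, which still converges geometrically. An alternative combination rule — the sigmoid of the
weighted logits instead of the weighted mean of sigmoids — is available via
`combine="sigmoid_of_mean"` for comparison; the convex combination of
probabilities is the default because it keeps the output a proper mixture
and makes the uniform-weight case exact model averaging.

Weights are reported as percentages per finding with largest-remainder
rounding at one decimal, so every printed row totals exactly 100.0.

## Base classifiers and training protocol

Each scale's classifier is a small convolutional network written in numpy
(`scalestack.nn`): three stride-2 3×3 convolution blocks, global average
pooling, and a linear multi-label head. Two deliberate design choices make
it a competent *energy* detector at desk scale:

* the first block's activation is `x → x²` rather than ReLU, turning the
  block into a learned quadrature-energy filter that detects band-limited
  texture regardless of phase and orientation;
* first-layer kernels are initialized zero-mean (zero DC gain), so smooth
  background shading is rejected from step one and the optimization does
  not have to discover bandpass structure from a cold start.

Training: Adam on mean binary cross-entropy over findings; the learning
rate is multiplied by 0.5 whenever the validation loss fails to improve for
3 consecutive epochs; training stops after 10 epochs without validation
improvement; the best-validation parameters are restored at the end.
Findings that are all-positive or all-negative in the training split are
trained through (the loss is well defined) but excluded from AUC reports
with a warning.

The per-resolution learning-rate/batch table for the large-scale regime
(256→0.0051/512, 512→0.00034/256, 1024→0.000181/180, 2048→0.0000918/75)
ships as the default `TrainConfig`. Those values target a large pretrained
backbone; the desk-scale benchmark (resolutions 32–256, tiny backbone,
training from scratch) uses its own documented setup: learning rate 0.002,
batch size 32, at most 20 epochs, channels (8, 16, 16), widened to
(16, 32, 32) at resolutions ≤ 32 where compute is negligible and the extra
filters stabilize low-band motif learning. Both tables are keyed by
resolution and coexist.

Data layout: a shared test set of 20% of the images; the remaining 80% is
split 90–10 into train/validation, with five rotating disjoint validation
blocks forming the five folds. The benchmark and the acceptance script
train fold 1; the fold machinery supports all five.

## The synthetic benchmark

Real multi-label radiograph corpora are restricted, so the pipeline is
validated on generated images whose discriminative signal is *constructed*
to live at known scales:

* images are 256×256, 8-bit: a flat base level (120) + a smooth random
  field (3×3 Gaussian grid upsampled bicubically, amplitude 12) + white
  pixel noise (σ = 20) + band-limited mid-frequency clutter (difference of
  Gaussians, σ = 6). The clutter matters: plain white noise averages away
  under downsampling, which would leave the coarse pyramid levels
  unrealistically clean and make low-band motif detection an all-or-nothing
  cliff instead of a graded task;
* **texture components** paint a Gaussian-windowed, randomly oriented
  sinusoid at 0.375·s/256 cycles/pixel for band scale `s` — above the
  Nyquist limit of the next-coarser pyramid level, so anti-aliased
  downsampling below `s` removes the component exactly, while every scale
  ≥ `s` retains it. Because downsampling also averages the pixel noise,
  the signal-to-noise ratio peaks near the band's own scale;
* **blob components** paint large low-contrast Gaussian blobs (diameter
  ≥ 25% of the image) that are buried in per-pixel noise at native
  resolution — detection requires large-area averaging, which only the
  coarse models can perform — and prominent at the coarsest scale;
* every finding is a *multi-component signature*: a primary motif at its
  affinity scale plus one or two weaker components at complementary
  scales, each with an independently drawn per-image contrast. The
  independence is the point — a stacked ensemble profits only from views
  whose errors decorrelate. Nested views of a single motif (a coarse band
  seen by a finer model) are strongly correlated and contribute almost
  nothing, which is measurable in this generator's data: the residual
  correlation between a finding's top two views predicts its achievable
  ensemble gain almost exactly;
* the finest-affinity texture cannot receive an independent *texture*
  second view (any coarser band is also visible to the top-scale model),
  so its second view is a dim blob population — only coarse models see
  blobs at all, and the brightness separation from the blob finding's own
  brighter blobs keeps the two findings distinguishable at the coarse
  scale;
* contrast ranges were chosen so that each finding's primary view reaches
  a test AUC around 0.85 and its secondary views sit roughly 5–8 AUC
  points below: a larger gap makes the cross-entropy-optimal stacking
  weights collapse onto the single best scale (no mixture, no gain), a
  smaller one makes the learned argmax scale unstable under
  validation-sample noise.

What the generator does *not* emulate: anatomy, label co-occurrence
structure, scanner artifacts, and inter-reader label noise. Passing the
benchmark therefore demonstrates that the stacking machinery recovers and
exploits scale-specific signal when it exists, not that any particular
clinical performance would be reached on real data.

A separate contamination model (`NoiseSpec`) adds quasi-periodic cosines,
Gaussian noise, and impulse ("salt-and-pepper") noise for the denoising
front-end; generation retains the clean image as the PSNR reference.
Patch extraction crops random 113×113 windows, with at most 70% of the
proposals (default 10 per image) emitted after deduplication and shuffling.

## Denoising front-end

Quasi-periodic interference concentrates in isolated Fourier bins. Bins
are flagged when their amplitude exceeds `threshold ×` the median amplitude
outside a small guard band around DC; the default threshold is 30 and is
user-overridable. The threshold multiplies the *median linear amplitude*
because absolute spectral amplitude scales with image size; with this
reading the default flags a 40-level sinusoid's two conjugate bins on a
typical 8-bit image and flags nothing on clean images. The mask is
symmetrized under frequency negation (conjugate symmetry of real images)
and never contains DC.

Flagged bins are attenuated by a Butterworth notch-reject bank,
`H = Π_k 1/(1 + (D0/D_k)^(2n))`, radius `D0 = 2` bins; the response is 0 at
each notch center and tightens as the order `n` grows. The order is chosen
by a lion optimization search (population 16, 4 prides, 25% rovers):
rovers mutate by ±1 order steps and challenge the weakest resident of a
random pride, replacement requires strict fitness improvement, the pride
count stays constant, and the search stops after 3 consecutive rounds
without improvement of the best PSNR. The initial population is spread
across the bank (every candidate seeded when the population allows), so on
small banks (≤ 12 candidates with the default population) the search
provably returns the exhaustive PSNR maximizer; on larger banks the
mutation walk is a genuine search. Fitness is PSNR = 10·log10(255²/MSE)
against the clean reference when one exists (the synthetic setting) or
against a 3×3 median-filtered copy of the input as a no-reference proxy.
Identical images report a +∞ sentinel.

## Effective receptive field

For a trained model run in evaluation mode, the ERF estimator
backpropagates one gradient per image from the center pixel of the final
convolutional layer's activation to the input, squares the gradients
elementwise (signed contributions would cancel), and averages over images
× channels — an uncentered sample variance of input sensitivity.
Normalization is by images × channels; input channels are summed after
squaring. Optionally each image is first shifted by uniform random integer
offsets up to ±25% of the side with reflection padding ("large random
translations"), decoupling the estimate from one alignment. An unsquared
signed average is available behind `squared=False` for comparison with the
original formulation.

`erf_summary` reports the area of pixels ≥ 50% of the peak and the radius
of the equal-area disk, in pixels and as a fraction of the image side. A
geometric receptive-field calculator provides the theoretical bound; the
estimated support is always contained in it (exactly, not approximately —
gradients outside the geometric cone are identically zero).

## Numerical choices and degenerate inputs

* Min-max normalization maps constant images to all zeros; rounding of
  intensities is half-up throughout.
* The photometric-polarity rule flips when the mean of a 10%-wide border
  frame exceeds the central half-region mean by > 20 levels (radiograph
  background is air and should be dark); the operation is idempotent.
* CLAHE uses clip limit 2.0 and an 8×8 tile grid by default; the clip
  value follows the convention where the per-bin clip count is
  `clip × tile_pixels / 256`.
* ImageNet channel constants: means (0.485, 0.456, 0.406), stds (0.229,
  0.224, 0.225); grayscale is replicated to three channels.
* JPEG export uses quality 96 (the quality factor must be an integer).
* Stacking ensemble probabilities are clipped by an ε = 1e-12 only inside
  the log; weights are re-derived from `V` at every step.
* AUC uses the rank-based Mann–Whitney statistic with average ranks, so
  ties count 1/2; single-class inputs are rejected. Fold aggregation uses
  the sample (n−1) standard deviation.
* All randomness flows from explicit integer seeds (dataset, splits,
  initialization, LOA); identical seeds give bit-identical artifacts, and
  a run can be reproduced exactly from its manifest.

## Problem sizes

The benchmark experiment uses n = 2000 images, scales 32/64/128/256, one
fold, up to 20 epochs per scale, and 100 stacking epochs; it completes in
roughly ten minutes on one CPU core. The fixture datasets in the test
suite use 60–1000 images at resolutions 32–128.

## Known limitations

* Per-finding ensemble gains on the benchmark carry run-to-run variance of
  roughly ±0.5 AUC points from training stochasticity alone (weight
  initialization, batch order, early-stopping epoch). The *average* gain
  across findings is comfortably positive under every seed we probed; the
  *minimum* over findings — dominated by the finest-affinity texture,
  whose independent coarse view is intrinsically the weakest — can dip
  toward zero for unlucky seeds. Fold-averaged evaluation (all five folds)
  would shrink this variance at five times the training cost.

* The numpy backbone is deliberately small; it demonstrates the stacking,
  ERF, and denoising machinery rather than competing with large pretrained
  networks. The training interface is backbone-agnostic.
* The LOA search space is one-dimensional (filter order), as the method
  defines it; the algorithm structure supports richer candidate encodings
  but none are implemented.
* Ensemble gains on the benchmark quantify variance reduction plus
  cross-scale complementarity under the generator's assumptions; absolute
  AUC values have no clinical meaning.
* With a single configured scale the pipeline skips stacking and reports
  the single model (a degenerate ensemble) with an explicit notice.
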