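# Methods

## Problem and model

`vesselseg` segments blood vessels in 2-D grayscale medical images
(CTA-style slices, or retina-style photographs after intensity
preprocessing). Vessels are thin, branching, multiscale structures — from
1–2 px capillary-like threads up to ~15 px trunks — and standard
encoder-decoder segmenters tend to lose the thinnest ones. The network
addresses this with attention-based skip connections and a dilated-pyramid
bottleneck:

* **RFU encoder.** Each encoder stage is a ReLU feature unit,
  `ReLU(BN(Conv3x3(x)))`, applied twice per stage by default (a single-unit
  mode exists). Stages are separated by 2x2 max pooling; stage *k* has
  `base_channels * 2^k` channels. Depth 4 is the default for CTA-like
  axial slices; depth 3 suits smaller retina-style images. Plain conv-BN-ReLU
  units are used instead of pretrained residual blocks: medical images are
  out of distribution for ImageNet weights, and the lighter encoder trains
  faster with fewer parameters.

* **SEPP bottleneck.** Four parallel branches over the deepest features:
  a 1x1 convolution, and three dilated 3x3 convolutions at rates 6, 12 and
  12, each followed by a squeeze-and-excitation channel gate and a 1x1
  convolution with ReLU. Branch outputs are concatenated and reduced back to
  the deepest encoder width by `BN(Conv1x1)`. The duplicated rate 12 is kept
  deliberately (the rate list is configurable, e.g. to the classic 6/12/18).
  The SE gate is `sigmoid(FC2(ReLU(FC1(globalavg(x)))))` with reduction
  ratio 16 (clipped so the bottleneck keeps at least one unit); gating is
  applied after the dilated convolution, with a switch for the reverse
  order.

* **SCA decoder.** Each decoder level fuses the running high-level map
  `X_hig` with the same-resolution encoder skip `X_low`:

      y = aver(mu) * X_low + upsample(X_hig'),

  where `X_hig' = Conv1x1(X_hig)` reconciles channel counts, `mu` is the
  non-local self-attention of `X_hig'` (row-softmax affinity over all
  spatial positions, value aggregation, element-wise product with the
  input), `aver` is global average pooling producing one gate per channel,
  and `upsample` is bilinear (chosen over transposed convolution to avoid
  checkerboard artifacts). A `BN(Conv1x1)` refinement follows the first
  fusion, and a final 1x1 convolution produces two-class logits with a
  softmax; the vessel-class probability map is exported.

## Numerical and design choices

* **Numerical core.** All tensor operations (convolution with dilation,
  batch norm, pooling, bilinear resize, softmax attention) and reverse-mode
  differentiation are implemented in `vesselseg.autodiff` on numpy, with
  convolutions as im2col GEMMs and input gradients computed as convolutions
  with the flipped, channel-transposed kernel. Gradients are verified
  against central finite differences in float64.
* **Attention weight shapes.** The attention projections are channel-space
  1x1 convolutions (queries/keys reduced to `C/8` channels, minimum 1), the
  standard non-local formulation.
* **Attention budget.** Self-attention is O(N^2) in N = H*W. Above a
  budget of 4096 positions the attended map is average-pooled by 2 until it
  fits; the channel gate consumes only the spatially pooled result, so the
  fusion output keeps its resolution.
* **Initialization.** He-normal for ReLU-followed convolutions, Xavier-style
  gain 1 for the linear 1x1 projections, and **zero** for the attention
  value projection: an untrained SCA block is then exactly the bilinear
  upsampling skip, and attention strength is learned from zero. Without
  this the multiplicative gate path inflates activations multiplicatively
  across decoder levels and training stalls in saturated softmax regions.
* **Batch norm** uses per-batch statistics in training and running averages
  (momentum 0.1, epsilon 1e-5) in inference.
* **Loss.** Weighted cross-entropy, mean over pixels of
  `-w_c(p) log p_c(p)`; class weights default to inverse class frequency
  measured on the training split (vessels are a small minority class).
* **Optimizer.** Adam (lr0 1e-3, beta1 0.5, beta2 0.999) with epoch-level
  poly decay `lr0 * (1 - epoch/max_epochs)^0.9`. The decay formula is also
  available in a literal alternative parenthesization behind an audit flag;
  the default matches the schedule's stated boundary behaviour (lr0 at
  epoch 0, 0 at the final epoch). 80/20 train/validation split; the
  best-validation-Dice checkpoint is retained.
* **Metrics.** DSC, mean IoU over both classes (foreground-only IoU also
  reported), sensitivity, accuracy, and rank-based AUC (ties half-counted,
  equal to trapezoidal ROC integration; undefined for single-class truth).
  Ratios with empty denominators are defined as 1 (agreement on absence).
  Test-set aggregation is micro (pooled counts) by default; macro is
  available.
* **Post-filter.** Connected components (8-connectivity by default) whose
  pixel count is strictly below 0.03% of the total predicted foreground are
  removed — the vascular tree is connected, so tiny disconnected islands
  are mis-segmentation noise. The threshold is per-component relative to
  total foreground; an absolute-pixel mode exists. The filter never adds
  pixels and is idempotent.

## Synthetic phantoms

Real CTA/fundus vessel data cannot ship with the package, so every stage is
exercised on generated phantoms with exact ground truth:

* Centerlines are cubic-spline-smoothed random walks started on the image
  border (subsequent branches fork from points on earlier ones), with
  heading diffusion proportional to the `tortuosity` parameter.
* Widths are sampled per branch from `width_range` and taper linearly
  toward the tip (to 40% of the base width, floor 1 px), creating
  within-branch multiscale structure.
* Intensities: per-branch foreground levels from `[0.55, 0.9]`, a scalar
  background from `[0.1, 0.4]`, plus a smooth random bias field (amplitude
  0.15, Gaussian-filtered noise at sigma = side/4) and i.i.d. Gaussian
  noise (sigma 0.05 by default). The bias field emulates the slowly varying
  illumination/contrast of angiographic slices and prevents the classes
  from being perfectly separable by a single global threshold. A
  `dark_vessels` flag inverts the image for fundus-like appearance.
* Optional distractor blobs (at most 3 px, placed clear of the vessels) add
  disconnected mask components for post-filter testing.
* All randomness flows through one `numpy.random.Generator`; a (config,
  seed) pair reproduces a sample bit for bit.

What the phantoms do **not** model: partial-volume effects, anatomy,
vessel crossings in projection, scanner-specific noise spectra, or fundus
color characteristics. Results on phantoms demonstrate that the
architecture, losses, metrics and pipeline are implemented correctly and
that the network can learn structure a global threshold cannot express;
they are not a claim about clinical-data accuracy.

## Data pipeline

Training-time augmentation for volume-style slices is geometric only:
rotation in [-15, 15] degrees, isotropic scaling in [0.9, 1.1], vertical
flips with probability 0.5 — applied identically to image and mask (mask by
nearest-neighbour, so it stays binary; exact right-angle rotations use
lossless `rot90`). Fundus-style photographs are intensity-preprocessed in
the order grayscale conversion (Rec.709 luminance), per-image
standardization (per-image because patch extraction follows), CLAHE (clip
limit 0.05, 8-px tiles — a moderately strong local equalization for
low-contrast vasculature), and gamma adjustment. Training crops are
128x128 patches whose centers are uniform over the full image; windows
overhanging the border are shifted fully inside by default (a zero-padding
mode exists), avoiding invented padding values.

## Study problem sizes

The end-to-end study trains a depth-3, base-16 network on 200 phantoms
(64x64) for 20 epochs at batch size 8 and evaluates on 50 held-out
phantoms against the best global-intensity-threshold baseline (threshold
scanned on the test set itself, which biases the baseline upward — the
learned model must beat a favoured baseline). These sizes keep the full
study in the minutes range on a single CPU while leaving the optimizer
configuration identical to the full-scale recipe.

## Known limitations

* Stride-1 'same' convolutions only; no transposed convolutions (bilinear
  upsampling by design) and no 3-D kernels.
* The O(N^2) attention is exact only up to the budget; larger maps are
  pooled first.
* Training is single-process and CPU-oriented; no warmup, no distributed
  training, no early stopping beyond best-checkpoint retention.
* The GC-Net weighting scheme for the cross-entropy is cited in the
  literature without a formula; inverse class frequency is used as the
  default substitute and is overridable.
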