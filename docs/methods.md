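# Methods

## Problem setting

Accelerated 2D MRI acquires only a fraction of the phase-encode rows of
k-space; the inverse Fourier transform of the zero-filled (ZF)
measurement is an aliased image. A convolutional network can be trained
to map the ZF image back to a de-aliased one, but such networks are
domain-specific: a model trained on one contrast, slice orientation or
anatomy degrades on another, and full fine-tuning (FT) of all weights on
a small target dataset both overfits and erases source-domain competence
(catastrophic forgetting).

This package implements *linear fine-tuning* (LFT): the pretrained
convolution weights `W` and biases `b` are frozen, and each
(filter, input-channel) kernel receives two trainable scalars — a
multiplicative scale `phi_W` and an additive shift `phi_b`. The forward
pass of such an SS ("scale-and-shift") convolution is

    V[n] = sum_m phi_W[n,m] * (U[m] ⊛ W[n,m]) + b[n] + sum_m phi_b[n,m]

The motivating hypothesis is that related MR domains share low-level
("basic") convolutional features, and differ mainly in how those
features are linearly recombined into "advanced" feature maps; scaling
per-kernel responses and shifting the bias is exactly a re-weighting of
that linear combination. Because a scalar commutes with convolution, the
factors fold into the weights (`phi_W[n,m] * W[n,m]`, bias
`b[n] + sum_m phi_b[n,m]`), so a trained SS network can be deployed as a
plain network with zero overhead. The package verifies this fold
equivalence numerically rather than assuming it.

Five regimes are compared on a common target test set: PT (pretrained
model evaluated directly), DT (trained from scratch on target data
only), FT (all weights fine-tuned), RFT (one scale per kernel *row* —
an intermediate granularity), and LFT. Per layer of shape
`(N, M, k, k)` the trainable-parameter counts are `N(Mk^2+1)` for
DT/FT, `NM(k+1)` for RFT, and `2NM` for LFT.

## Conventions and representations

- Convolution is cross-correlation (no kernel flip), zero "same"
  padding, stride 1 (stride 2 only in encoder downsampling) — the
  deep-learning convention. Even-sized kernels are rejected rather than
  padded asymmetrically.
- The filter bank stores one bias per filter. Where the per-kernel
  decomposition needs a per-kernel bias, the filter bias is distributed
  equally over the M kernels (`b/M` each), which keeps the
  "advanced = sum of basic features" identity exact while matching the
  conventional layer shape; per-kernel shifts aggregate additively into
  the effective bias, which is algebraically identical to applying them
  per kernel.
- The scale factor multiplies weights only, never the bias.
- RFT as described elsewhere defines only row scales; a per-kernel
  shift (as in LFT) is included here so RFT strictly interpolates
  between FT and LFT granularity. It can be excluded by zeroing and
  not selecting the shifts.
- Complex images are carried as 2 real channels; metrics are computed
  on magnitude images normalized to [0, 1].
- Numerical tolerances: identity-insertion and decomposition contracts
  hold bitwise (identity factors multiply by exactly 1.0); two-route
  equivalences (per-response scaling vs. weight folding) are asserted
  at 1e-5 in single precision and 1e-10 in double.

## Forward model

`to_kspace` is the centered orthonormal 2D DFT (DC at `(h//2, w//2)`,
unitary scaling so Parseval holds); undersampling zeroes unselected
phase-encode rows (axis 0); ZF reconstruction is the magnitude of the
centered inverse DFT.

Masks are variable-density 1D Cartesian: exactly `round(rate*height)`
rows, with a contiguous band of `round(center_fraction*height)` rows
around DC always sampled, and the remainder drawn without replacement
with probability proportional to a Gaussian of standard deviation
`sigma_fraction*height` centered on DC. Defaults `center_fraction =
0.08` and `sigma_fraction = 1/6` follow common variable-density
practice; the underlying sampler is known only to be "normal-density,
denser at the center", so these two knobs are exposed and documented
rather than claimed canonical. If the Gaussian weights of all remaining
candidate rows underflow to zero, selection falls back to uniform.

## Reconstruction network

A compact residual U-net generator built entirely from plain conv
banks, so SS blocks insert into every learnable layer:

- head conv (2 -> C channels), `depth` encoder levels of
  [conv, strided conv doubling channels], a bottleneck conv, `depth`
  decoder levels of [nearest-neighbor upsample, conv halving channels,
  additive encoder skip, conv], and a zero-initialized linear tail
  feeding a global residual skip (`output = input + correction`).
  Defaults: depth 2, C = 8, kernel 3x3, leaky-ReLU slope 0.2,
  He-normal init, one chain (a second chained U-net is available).
- The zero tail makes the fresh network the identity map, so training
  starts from the ZF baseline, and an identity-initialized SS network
  starts exactly from the pretrained model's behavior (verified
  bitwise: scaling by 1.0 and adding 0.0 are exact in IEEE
  arithmetic).
- The original GAN-based reconstruction architecture this stands in
  for (residual bottleneck blocks, a chained generator, an adversarial
  discriminator) is deliberately simplified: the transfer method is
  architecture-agnostic, and a generator of basic units keeps every
  contract checkable. The `use_adversarial` flag is reserved and
  currently rejects construction; training losses are pixelwise.

The network, backpropagation, and Adam are implemented directly in
NumPy. At these layer sizes a self-contained implementation is fast
enough, keeps the dependency surface minimal, and makes training
bitwise reproducible on CPU — which the freezing and determinism
contracts test literally (tensor hashes before/after training).
Gradients were validated against central finite differences through
every op (conv, strided conv, leaky ReLU, upsampling, skips, both loss
terms). The generator runs in single precision by default; a double
path (`dtype=np.float64`) exists for tight-tolerance verification.

## Training protocol

- Optimizer: Adam (beta1 0.9, beta2 0.999, eps 1e-8). Initial learning
  rate 1e-4 for pretraining. Transfer defaults: 1e-4 for LFT/RFT/DT,
  1e-5 for FT — fewer trainable parameters tolerate larger steps; all
  configurable.
- Loss: L1 on the magnitude image by default; L2 and an optional
  k-space data-consistency penalty (squared deviation on sampled rows,
  weight 0.1) are available.
- Early stopping: training stops when validation PSNR has not
  *strictly* improved for `patience` epochs (default 15); ties do not
  advance the best epoch. The returned model is the
  best-validation-PSNR checkpoint.
- Data split: deterministic 16:5:4 train/val/test with
  largest-remainder rounding; training-set-size sweeps subset the
  train portion only.
- Freezing contracts: under LFT/RFT only the factor arrays are passed
  to the optimizer; the backbone is untouched by construction and its
  SHA-256 hashes are compared before/after training in the tests.
- One mask per sampling rate is fixed across a run (models are
  compared per rate); per-sample masks would conflate mask variance
  with strategy differences at this scale.
- Every source of randomness (init, batch order, mask, phantoms) flows
  from explicit integer seeds; identical configs reproduce bitwise.
- A transfer run evaluates validation PSNR once before the first step
  ("epoch 0"); with identity factors this equals the PT model's score
  exactly, which the tests assert.

## Metrics

- PSNR: `10 log10(data_range^2 / MSE)`, `data_range` 1.0 by default;
  identical images yield an `inf` sentinel that reporting excludes
  from mean ± std with a count.
- SSIM: Wang et al. convention — 11x11 Gaussian window, sigma 1.5,
  k1 = 0.01, k2 = 0.03, Gaussian-weighted (uncorrected) local moments,
  border cropped so only fully supported windows are averaged. The
  implementation is cross-checked against scikit-image in the tests.
- WPSNR: PSNR with a weighted MSE under a nonnegative mean-1 map. The
  published variant this gestures at is not fully specified in
  accessible sources, so the default map is an explicitly in-house,
  contrast-sensitivity-inspired choice: weights decrease with local
  high-frequency energy of the reference (visual masking), normalized
  to mean 1 so that uniform weighting reduces WPSNR to PSNR exactly.
  User-supplied maps take precedence. WPSNR values should be compared
  only within this package.
- Tables report mean ± sample standard deviation (ddof 1) per model
  and metric over the test set.

## Synthetic domains

Real multi-site MR data is replaced by parametric phantoms: composites
of ellipses (brain) or stripes and elongated ellipses (knee) over five
tissue labels (background, outer, matter_a, matter_b, lesion), rendered
through an injective label-to-intensity contrast map, with per-slice
geometry jitter and a smooth multiplicative bias field (amplitude 0.1)
to break piecewise-constancy. Background stays exactly 0. Slices are
deterministic in (seed, index).

The three transfer scenarios mirror increasing domain distance:

- **contrast**: same geometry, T1-like vs T2-like intensity maps (the
  matter_a/matter_b ordering inverts) — label maps identical at
  matched indices;
- **direction**: sagittal-like vs axial-like brain templates;
- **anatomy**: brain vs knee templates — the largest geometric shift.

The tests assert this ordering via mean per-class Dice between matched
label maps. What the phantoms preserve is exactly the statistical
structure the method's hypothesis needs: shared low-level features
(edges, ellipse boundaries, smooth shading) whose combination into
images shifts across domains. What they do not model: MR noise
statistics, coil sensitivities, relaxation physics, realistic texture.
Consequently, passing results demonstrate the *mechanics and contracts*
of the transfer strategies (freezing, identity start, parameter
economy, qualitative orderings) — not clinical-grade reconstruction
quality, and not the absolute PSNR/SSIM levels reported for real
datasets.

## Desk-scale experiment sizes

The scenario runner defaults to 64x64 slices (divisible by 2^depth),
a depth-2, 8-channel generator (~7.7k weights), a 160-slice source
domain and smaller target domains, batch size 4–8, and the patience-15
early-stopping rule with generous epoch caps (200 pretraining, 150
transfer). One adaptation deserves emphasis: the protocol learning
rates above (1e-4 pretraining, 1e-5 FT) presuppose epochs of thousands
of optimizer steps over large datasets. A desk-scale epoch is ~5–15
steps, so the scenario runner scales all step sizes tenfold (1e-3
pretraining and LFT/RFT/DT transfer, 1e-4 FT) — otherwise the source
model stays far from convergence and every transfer comparison
degenerates. The library-level defaults in `StrategyConfig` keep the
unscaled protocol values; the scaling is a property of the desk-scale
scenario configuration and is overridable there. The source model is
pretrained once per sampling rate and shared by all transfer runs at
that rate, matching the one-source-model protocol; transfer-phase
variation across seeds covers initialization (DT) and batch order.
256x256 slices and deeper/wider nets are reachable through
configuration.

## Known limitations

- The NumPy training loop is single-threaded and CPU-bound; it is
  sized for phantom studies, not for real datasets.
- WPSNR is an approximation unique to this package (see above).
- Adversarial and perceptual losses are not implemented; the stand-in
  generator is far smaller than published reconstruction GANs.
- Only single-coil, Cartesian 1D undersampling is modeled; no noise is
  injected in k-space.
- RFT's shift handling (included by default) is one of two defensible
  readings of the row-granular scheme.
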