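# Methods

This note documents the model, the numerical choices behind the
implementation, what the synthetic phantoms do and do not emulate, and
the scales at which the shipped experiments run.

## Problem setting

Three training subsets drive the method: labeled source-domain volumes
`SL`, a small labeled target subset `TL`, and a larger unlabeled target
subset `TU`.  The goal is voxel-wise segmentation of four abdominal
organs (liver, right kidney, left kidney, spleen; class 0 is background)
in the target domain, where labels are scarce.  Source and target differ
in their per-organ intensity distributions (e.g. CT versus T2-SPIR MRI)
and in apparent organ scale across patients.

## Model

The segmentation network is a 3D UNet over volumes normalized to [0, 1].

* **Domain-specific batch normalization (DSBN).**  Each normalization
  layer on the encoder path stores running statistics *and* affine
  parameters separately per domain; the forward pass selects the branch
  by the sample's domain tag.  All other weights are shared.  We read
  the normalization denominator as √(variance + δ) with δ = 1e-5, the
  standard form, and use running-statistic momentum 0.1.  The affine
  scale/shift are per-domain (following their per-domain subscripts in
  the defining equations).  Mixed-domain batches must be split before a
  DSBN layer; the trainer always forwards per-domain sub-batches.
* **SAD encoder blocks.**  Conv-D (conv → DSBN → ReLU) stem, then two
  parallel dilated 3×3×3 branches with rates (1, 3), each emitting half
  the block width (so their concatenation restores it) and gated by an
  independent squeeze-and-excitation module (reduction 4); channel
  shuffle with 2 groups (one per scale branch) mixes the scales before a
  closing Conv-D.  Kernels are 3×3×3 with isotropic dilation; with
  strongly anisotropic spacing an in-plane-only dilation would be a
  reasonable variant, but the shipped phantoms are processed on their
  native grid.
* **GLF bottleneck.**  A local path (3×3×3 → 1×1×1 conv at width
  d = C_in/2) parallel to a global path: 1×1×1 projection to d, unfold
  into 2×2×2 patches giving a (B, P=8, N, d) tensor, L = 4 pre-norm
  transformer layers, fold back.  Attention runs over the N patch
  positions with per-head width d_head = 8 and n_head = d/d_head (the
  head count is derived, not free); softmax over the key axis scaled by
  1/√d_head; no positional embeddings, so the transformer is
  permutation-equivariant over patch positions (a property the tests
  assert).  The MLP expansion factor is 2 with GELU; LayerNorm acts on
  the feature axis only; no dropout (the small-data regime is handled by
  augmentation).  The two paths are concatenated (2d channels) and fused
  by a shared 3×3×3 then 1×1×1 convolution — the fusion order is the one
  reading of the architecture under which the tensor shapes compose.
  GLF's internal convolutions are normalization-free and domain-agnostic;
  domain awareness lives in the encoder.
* **Topology.**  Defaults: 4 stages, base width 16 doubling per stage,
  downsampling by stride-2 Conv-D, upsampling by trilinear interpolation
  + convolution, plain (single-statistics) batch normalization in the
  decoder, shared softmax head over 5 classes.  Stage count, widths and
  a single- vs double-conv decoder are configurable; the desk-scale
  experiments below use 3 stages at base width 4.

## Training

* **Losses.**  Supervised: 0.7 · (1 − mean multi-class soft dice) +
  0.3 · cross-entropy, averaged over the labeled samples of the step
  (SL and TL forwarded separately because of DSBN, then combined by
  sample count).  Consistency: voxel/class MSE between student and
  teacher probabilities on identical TU volumes under independently
  drawn input noise; the teacher output carries no gradient.
* **Consistency schedule.**  The warm-up 0.1·e^(−5(1−k/k_max)²) is
  exposed as `consistency_weight`.  Because the tuned trade-off λ = 2.0
  and the printed ramp amplitude 0.1 cannot both be the final weight, we
  normalize the ramp by its amplitude so the applied weight is
  λ_eff(k) = λ·e^(−5(1−k/k_max)²), reaching exactly λ at the final
  iteration — the standard mean-teacher reading.  Both the amplitude and
  λ remain configurable.
* **Noise Δ, Δ′.**  Additive Gaussian input noise (sd 0.05) drawn
  independently for student and teacher, on top of one *shared* online
  augmentation of the unlabeled volume (in-plane rotation ±30°, shear
  ±0.1 rad, gamma ∈ [1.5, 2]; geometric parts hit image and label
  identically, labels by nearest neighbour).  The geometric transform is
  shared by the pair on purpose: the consistency loss is a voxelwise MSE,
  which is only meaningful when the two predictions are spatially
  aligned; the stochastic disagreement the teacher must smooth out comes
  from the independent input noise.
* **Optimization.**  AdamW, lr 9e-4, weight decay 5e-5, stepwise
  exponential decay ×0.95 every 250 iterations; batch composition
  4 SL + 2 TL + 2 TU; EMA decay η = 0.99 with the teacher initialized as
  a copy of the student; teacher buffers (running statistics) follow the
  same EMA rule; global gradient-norm clipping at 5 keeps rare spikes
  from aborting a run.  The TL and noised-TU target samples share one
  forward pass, so the target batch is normalized jointly.
* **Determinism.**  All randomness derives from one seed through
  separate streams (init / batch sampling / supervised augmentation /
  consistency noise), so disabling the consistency machinery reproduces
  the λ = 0 supervised trajectory exactly — a property under test.

## Numerical engine

The network runs on a small reverse-mode autodiff core written on numpy
(`ssdaseg._tensor`, `ssdaseg.nn`).  3D convolution offers three
equivalent compute paths — an im2col/GEMM reference, an rFFT-based
spectral path, and a pointwise GEMM for 1×1×1 kernels — that agree to
float rounding (asserted in tests); the dispatcher prefers the spectral
path except on very small grids, where direct gathering is cheaper.
Softmax is computed in shifted (stable) form, so probabilities remain
finite for arbitrarily scaled inputs.  Floating dtype follows the
caller: network weights are float32; accuracy-critical closed-form
checks (e.g. the EMA recursion) run in float64.

## Synthetic phantoms

`ssdaseg.synthetic` generates the statistical structure the method
assumes, not anatomy: four axis-aligned ellipsoid organs at
anatomically-inspired anchor positions with per-case jittered centres
and per-case scale draws (liver large, kidneys small and mirrored,
spleen intermediate), on a 32×32×16 grid with anisotropic spacing
(1.5, 1.5, 5 mm).  Domain shift is realized as per-class affine
intensity remapping with inverted organ/background contrast between the
two domains (mimicking CT vs T2-SPIR), per-case class-mean draws
(patient variation) and voxel noise (sd 0.03), followed by per-case
min-max normalization.  The two kidneys are deliberately given nearly
identical intensities so that telling them apart requires spatial
context — the capability the global-fusion bottleneck exists for.
Per-case seeds are derived from (dataset seed, case index) by a
splitmix-style mixer, making datasets reproducible element-wise.

What the phantoms do **not** emulate: real anatomy and organ shape
variability, imaging physics (bias fields, partial volume, artifacts),
inter-organ contact surfaces, or registration mismatch between
modalities.  Passing the phantom study therefore demonstrates that the
machinery optimizes what it claims to optimize under a genuine
distribution shift — not clinical-grade accuracy.

## Metrics

DSC per organ; ASD in millimetres using 6-connectivity boundary voxels
and exact Euclidean distance transforms weighted by voxel spacing.
Conventions: DSC is 1 when both masks are empty and 0 when exactly one
is; ASD with an empty surface is flagged as undefined (never silently
zero).  Metrics are computed at the processing grid resolution with
header spacing.  Method comparison uses two-sided paired t-tests on
per-case organ-averaged scores; zero-variance differences yield a
flagged NaN rather than a fabricated p-value.

## Scales used by the shipped experiments

Full-size training (256×256×32 grids, 200 epochs) is a configuration
choice, not something the test suite runs.  The packaged study uses
32×32×16 phantoms, a 3-stage width-4 network with a single-conv decoder,
300 training steps at lr 3e-3 for the two-arm component comparison
(full method vs TL-only supervised, 3 seeds, 20 % labeled target data,
online augmentation as in the full recipe) and 400 steps without
augmentation for the single-case overfitting oracle.  One recipe
adaptation applies to the scaled runs: the learning rate is raised above
the full-schedule default (9e-4) because a few hundred iterations must
cover the distance the full recipe covers in thousands of iterations.
The recipe constants themselves (λ, λ_dice, λ_ce, η, batch composition,
augmentation ranges, decay schedule) are unchanged.  At this horizon the
comparison catches both arms mid-training; the consistency ramp is a
function of k/k_max, so it compresses onto the short schedule
automatically.

## Known limitations

* The desk-scale two-arm study is directional (full vs TL-only), not a
  reproduction of published effect sizes, and at this scale it can come
  out *against* the full method: the phantom family's inter-case
  variability is modest, so two labeled target cases already span much of
  the test distribution, and on a few-hundred-step horizon the EMA
  teacher (η = 0.99, a ≈100-step memory) lags a fast-improving student,
  making the ramped consistency term a drag rather than a regularizer.
  Semi-supervised domain adaptation earns its keep when target labels are
  genuinely insufficient and training runs long enough for the teacher to
  stabilize — conditions the miniature study deliberately does not
  guarantee.  The test suite runs the comparison and reports it as
  measured.
* Eval-mode predictions use running batch-norm statistics, which lag at
  very small step counts.
* DSBN supports exactly two domains; more would need a tag-indexed
  registry rather than the fixed source/target pair.
* MRI-style intensity clipping is not applied (only CT volumes are
  clipped, to ±350); percentile clipping would be a plausible extension.
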