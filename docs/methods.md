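# Methods

## The model

`sdnet` implements a semi-supervised *double-cooperative* training scheme
for 3D liver segmentation from CT. Two volumetric encoder–decoder
segmentation networks — a V-Net-style model `f_vnet` and a residual twin
`f_resvnet` — are trained jointly on a small labeled set
`D_L = {(x_i, g_i)}` and a larger unlabeled set `D_U = {x_j}`, where
`x ∈ R^{D×H×W}` is an intensity volume and `g ∈ {0,1}^{D×H×W}` a binary
organ mask. Every iteration draws a batch with equal parts labeled and
unlabeled volumes and routes it through both networks; each network's
softmax output `p(x) ∈ [0,1]^{2×D×H×W}` is a per-voxel two-class posterior.

**Supervised part (adaptive mask re-examination).** Both models predict the
labeled volumes. The *disagreement mask*

    dif = XOR( binarize(p_vnet(x)), binarize(p_resvnet(x)) )

marks the voxels where the binarized predictions differ — where at least
one model must be wrong. Each model minimizes

    L_s = L_CE + L_Dice + L_MSE^dif

with `L_CE` the mean voxelwise cross-entropy, `L_Dice = 1 − (2Σg·p_fg + ε)/(Σg + Σp_fg + ε)`
the soft Dice loss on the organ channel, and
`L_MSE^dif = mean_{v: dif_v=1} (g_v − p_fg(v))²` a mean-squared re-check of
the uncertain region against ground truth. The sum is unweighted. An
ablation flag (`dif_loss="weighted_ce"`) replaces the disagreement MSE with
an inverse-class-frequency weighted cross-entropy on the same region.

**Unsupervised part (dynamic pseudo-labels).** Each iteration, the model
with the smaller labeled-batch Dice loss is selected as the pseudo-label
*generator* (exact ties go to `vnet`; a fixed, documented rule). Its organ
posteriors on the unlabeled volumes are sharpened by the temperature
transform

    s(p) = p^{1/T} / (p^{1/T} + (1−p)^{1/T}),   T = 0.5 by default,

which implements entropy minimization: `T=1` is the identity, `T→0`
approaches hard thresholding at 0.5. The other model adds
`L_uns = mean_v (s(p_gen) − p_fg)²` on the unlabeled part. Pseudo-labels
are constants with respect to the generator: no gradient flows back
through them (verified by a dedicated test). Both models are then updated
independently by momentum SGD.

### Formula conventions

Some published statements of these quantities circulate with internal
inconsistencies; this package fixes the standard, self-consistent forms:

* the soft Dice numerator is the product `G·Ĝ` — a variant with a
  logarithm inside the numerator is not "one minus the Dice score" and is
  not used;
* both MSE terms are positive means of squares (a negated mean of squares
  is degenerate to minimize);
* specificity is `TN/(TN+FP)` — a `TP+FP` denominator, which one
  occasionally sees, measures nothing about the background class.

## Backbones

The two architectures share one topology: `depth` resolution levels with
one 3×3×3 convolution + instance norm + leaky ReLU block per level,
average-pool downsampling, nearest-neighbour upsampling with encoder skip
concatenation, and a 1×1×1 two-class softmax head. `resvnet` adds an
additive identity (or 1×1×1 projection) shortcut around every block; this
is the only difference, so the pair has matched capacity but distinct
optimization paths — the source of informative disagreement. Channel
widths are `width_scale · 2^level`.

Down/upsampling by pooling rather than strided and transposed
convolutions keeps the autodiff core small and the transforms exact;
at the organ scales used here the difference is immaterial.

The networks run on a package-internal NumPy reverse-mode autodiff core
(`sdnet.autodiff`) with numba-compiled 3D convolution kernels. Every
operation's gradient is validated against central finite differences
(relative tolerance 1e-4 on 2³ grids). Inputs must be normalized to
[0, 1] and spatial dims divisible by `2^(depth−1)`.

## Preprocessing and augmentation

CT volumes are clamped to a Hounsfield window and rescaled linearly to
[0, 1]. The default window is [0, 400] HU. Liver protocols are also
commonly stated as a display window of width 400 at level 0 (implying
[−200, 200]); the clip range is exposed (`hu_lo`/`hu_hi`) so either
convention is one flag away.

Train-time augmentation applies random axis flips and 90° rotations in
equal-extent planes — exact grid symmetries, so masks stay strictly binary
and no interpolation is introduced. The same transform is applied to a
volume and its mask; unlabeled volumes are augmented too (the training
input as a whole is flipped/rotated), which also diversifies the views on
which pseudo-label agreement is enforced.

## Optimization

Momentum SGD per model: lr₀ = 0.01 divided by 10 every 200 iterations
(1200 iterations total in the reference schedule), momentum 0.9, weight
decay 1e-4, batch 4 = 2 labeled + 2 unlabeled, sampling with replacement.
Numerical constants: Dice smoothing ε = 1e-5, log-clamp 1e-7 — both
unstated in the source and fixed here. An optional scalar weight on
`L_uns` (default 1.0, no ramp-up) and a `mutual` flag for symmetric
pseudo-label exchange (off by default; the literal reading trains only
the inferior model on pseudo-labels) are exposed for experimentation.

Open choices resolved here (alternatives were plausible): the generator is
re-selected *every iteration* from the current labeled batch's Dice losses
(cheap, "real-time"); no confidence threshold filters pseudo-labeled
voxels; pseudo-labels are recomputed fresh each step, never cached.

## The phantom benchmark

All tests and the acceptance script run on synthetic phantoms, not
clinical CT. A phantom is a lobed ellipsoid "liver" (semi-axes ~11/9/8
voxels in a 32³ grid, jittered centre, ~4 spherical surface lobes) at
~110 HU on a ~20 HU background, with iso-intense distractor spheres
placed 2–5 voxels from the organ surface, Gaussian partial-volume blur
(σ = 1.2 voxels) and additive 25 HU noise. Two heterogeneity parameters
emulate patient/scanner variability: each sample scales its semi-axes by
±22% and its organ and distractor contrasts independently by ±45%
(`shape_jitter`, `contrast_jitter`). The mask is always the exact
pre-blur organ indicator.

These defaults were chosen so the benchmark exhibits the failure modes the
method targets: intensity thresholding cannot separate organ from
distractors (iso-intense, independently contrast-jittered), boundaries are
genuinely ambiguous (blur + noise), and two labeled samples undersample
the shape/contrast distribution — full supervision on the ten-volume pool
measurably beats training on two labeled volumes, so headroom for
unlabeled data exists. What phantoms do **not** model: anatomical shape
statistics, intensity inhomogeneity fields, anisotropic spacing, lesions,
or inter-organ contact without any intensity gap. The benchmark shows the
machinery works end to end under controlled conditions; it is not
evidence of clinical-grade accuracy.

## Desk-scale problem sizes

The acceptance benchmark trains on 32³ phantoms with `width_scale=4`,
`depth=3` backbones for 300 iterations (two lr phases of the reference
schedule), 2 labeled + 8 unlabeled training volumes (the 20:80 ratio) and
8 test volumes; the supervised-only twin uses the same labeled volumes,
schedule and batch size with the unlabeled part removed. The
loss-stabilization check uses 16³ phantoms and `width_scale=2` for 300
iterations. These sizes are the package's chosen desk-scale operating
point; all of them are plain configuration values.

## Evaluation

Predicted masks come from binarizing the mean of the two models' organ
posteriors (`infer="mean"`; single-model inference is a flag). *Dice per
case* is the unweighted mean of per-volume Dice scores; *Dice global*
pools voxel confusion counts over all volumes first (large volumes
dominate). Sensitivity, specificity, accuracy and Jaccard are reported on
pooled counts, with per-volume rows available in the report. Ratio
metrics with a zero denominator return 1.0 (nothing to get wrong); in
particular Dice of two empty masks is 1.0. `binarize` breaks exact
probability ties toward background (conservative segmentation).

## Known limitations

* CPU-only, whole-volume training at small widths; no patching, mixed
  precision or multi-GPU.
* The phantom generator's realism limits, listed above.
* Generator selection uses batch-level Dice losses; a rolling average or
  held-out labeled set would be less noisy but costs extra passes.
* **The semi-supervised margin at desk scale is within noise.** Because
  `train()` uses separate random streams for the labeled and unlabeled
  pipelines, a supervised-only run with the same seed sees the identical
  labeled batches, augmentations and initializations, so the
  semi-supervised vs supervised comparison is paired in all exogenous
  randomness and isolates the causal effect of the unsupervised loss.
  Measured this way on the phantom benchmark, that effect on final test
  Dice is of order ±0.001–0.002 and its sign varies with the seed: the
  two models, trained on the same two labeled volumes, reach consensus on
  the unlabeled volumes within ~100 iterations, after which the
  pseudo-label MSE is nearly zero and contributes only a weak
  consistency tether. The benchmark therefore validates the mechanism
  (correct routing, selection, sharpening, gradient isolation — all
  oracle-checked) but does not demonstrate a reliable accuracy gain from
  unlabeled data at this scale; demonstrating that gain presumably needs
  the data diversity and model capacity of the full-scale setting, which
  is outside this package's desk-scale envelope.
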