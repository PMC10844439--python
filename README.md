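# sdnet — semi-supervised double-cooperative 3D liver segmentation

Dense voxel-level annotation of abdominal CT is the bottleneck of
learning-based liver segmentation: expert contours are slow and expensive,
while unannotated scans are plentiful. `sdnet` implements a
semi-supervised *co-training* scheme that turns that imbalance into
signal. Two volumetric segmentation networks — a V-Net-style
encoder–decoder `f_vnet` and a residual twin `f_resvnet` — are trained
together on a few labeled volumes plus many unlabeled ones:

* **Labeled volumes.** Both models predict each volume; the voxels where
  their binarized predictions differ form the *disagreement mask*
  `dif = XOR(binarize(p_vnet), binarize(p_resvnet))` — where at least one
  model must be wrong. Each model minimizes
  `L_s = L_CE + L_Dice + mean_{dif}(g − p_fg)²`, i.e. standard
  cross-entropy + soft Dice plus a mean-squared re-examination of the
  uncertain region against ground truth.
* **Unlabeled volumes.** Every iteration, the model with the smaller
  labeled Dice loss becomes the *pseudo-label generator*: its organ
  posteriors are sharpened by `s(p) = p^{1/T}/(p^{1/T} + (1−p)^{1/T})`
  (entropy minimization, `T = 0.5`) and the other model minimizes
  `L_uns = mean (s(p_gen) − p_fg)²` against them. Pseudo-labels carry no
  gradient to their generator, and the roles swap dynamically whenever
  the other model becomes the better one.

Everything runs on CPU from a built-in synthetic phantom generator —
lobed iso-intense organs with abutting distractor blobs, blurred
boundaries, noise, and per-sample shape/contrast heterogeneity — so the
whole pipeline is testable without downloading clinical data. The
networks run on a small package-internal NumPy autodiff core with
numba-compiled 3D convolutions. See `docs/methods.md` for the model
details and design rationale.

Intended users: researchers studying semi-supervised segmentation methods
who want a complete, inspectable, CPU-scale reference implementation, and
anyone needing the evaluation suite (Dice per case / Dice global,
sensitivity, specificity, accuracy, Jaccard) or the phantom benchmark on
their own data.

## Worked example

```python
from sdnet import TrainConfig, evaluate, generate_split, train
from sdnet.volume_io import clip_and_normalize

# 2 labeled + 8 unlabeled training phantoms (the 20:80 ratio), 2 test
split = generate_split(n_labeled=2, n_unlabeled=8, n_test=2, seed=7)
cfg = TrainConfig(total_iterations=60, width_scale=2, checkpoint_every=0, seed=7)
result = train(split, cfg)

test = [(clip_and_normalize(v), m) for v, m in split.test]
report = evaluate(result.models, test)
print(f"dice per case: {report.dice_per_case:.4f}")
print(f"dice global  : {report.dice_global:.4f}")
```

Running this (it is `examples/03_train_cotraining.py`, about a minute on
one CPU) prints:

```
iterations run       : 60
vnet dice loss       : 0.841 -> 0.327
resvnet dice loss    : 0.840 -> 0.108
disagreement fraction: 0.530 -> 0.014
vnet generated pseudo-labels in 0% of iterations
test Dice per case   : 0.8984  (mean of per-volume Dice)
test Dice global     : 0.8984  (pooled voxel counts)
```

The falling Dice losses show both models converging; the disagreement
fraction collapsing from 53% to under 2% of voxels shows them reaching
consensus; the residual twin was the better model throughout this short
run, so it generated all the pseudo-labels and the V-Net twin received
them; and a test Dice near 0.90 after only 60 iterations on two labeled
volumes is the co-training doing its job — the benchmark schedule
(300 iterations, width 4) reaches ~0.92–0.96 depending on the seed.

The other `examples/` scripts walk through phantom generation, the loss
suite, the metric suite, and the labeled:unlabeled ratio experiment.

## Command line

A thin CLI wraps the library for shell use:

```bash
sdnet phantoms --out data/ --n-labeled 2 --n-unlabeled 8 --n-test 2 --seed 7
sdnet train --config cfg.yaml --data data/ --out run/
sdnet evaluate --checkpoint run/checkpoint_001200.npz --data data/ --report report.csv
sdnet ratio-experiment --out sweep/ --ratios 20:80,50:50,100:0
sdnet version
```

Volumes and masks are NIfTI (`.nii`/`.nii.gz`); configs are YAML mirroring
`TrainConfig` field-for-field; checkpoints are NumPy `.npz` archives
holding both models' parameters and the iteration counter; every command
writes a JSON run manifest beside its outputs.

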