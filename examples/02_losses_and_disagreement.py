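"""The loss suite on a toy case: cross-entropy + soft Dice + disagreement MSE.

Two imaginary model predictions disagree on part of a small grid; the
disagreement mask marks those voxels and the supervised objective adds an
MSE term that re-examines exactly that region against ground truth.
"""

import numpy as np

from sdnet import (
    cross_entropy_loss,
    dice_loss,
    difference_mask,
    pseudo_label_mse_loss,
    sharpen,
    supervised_loss,
)

truth = np.zeros((4, 4, 4), dtype=np.uint8)
truth[1:3, 1:3, 1:3] = 1  # an 8-voxel cube of "organ"

rng = np.random.default_rng(0)
fg_a = np.clip(truth + rng.normal(0, 0.25, truth.shape), 0, 1)  # decent model
fg_b = np.clip(truth + rng.normal(0, 0.45, truth.shape), 0, 1)  # weaker model
pred_a = np.stack([1 - fg_a, fg_a])
pred_b = np.stack([1 - fg_b, fg_b])

dif = difference_mask(pred_a, pred_b)
print(f"disagreement voxels: {int(dif.data.sum())} of {truth.size}")

bundle = supervised_loss(pred_a, truth, dif.data)
print(f"model A: ce={float(bundle.ce):.4f} dice={float(bundle.dice):.4f} "
      f"mse_dif={float(bundle.mse_dif):.4f} total={float(bundle.supervised_total):.4f}")
# total is the exact unweighted sum of the three components

pl = sharpen(fg_a, T=0.5)  # soft pseudo-labels, pushed toward 0/1
print(f"sharpening: mean |p-0.5| before={np.abs(fg_a-0.5).mean():.3f} "
      f"after={np.abs(pl-0.5).mean():.3f}  (larger = more confident)")
print(f"pseudo-label MSE for model B: {float(pseudo_label_mse_loss(pred_b, pl)):.4f}")
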