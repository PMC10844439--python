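"""The evaluation suite: confusion counts and the six segmentation metrics.

Shows how Dice per case and Dice global diverge when volumes differ in
size and quality: the global score pools voxel counts, so large volumes
dominate it, while the per-case score weights every volume equally.
"""

import numpy as np

from sdnet import ConfusionCounts, accuracy, confusion, dice_score, jaccard
from sdnet import sensitivity, specificity

truth = np.zeros((8, 8, 8), dtype=np.uint8)
truth[2:6, 2:6, 2:6] = 1
pred = np.roll(truth, 1, axis=0)  # slightly offset prediction

c = confusion(pred, truth)
print(f"confusion: tp={c.tp} tn={c.tn} fp={c.fp} fn={c.fn}")
print(f"dice        : {dice_score(pred, truth):.4f}")
print(f"sensitivity : {sensitivity(c):.4f}   (organ voxels recovered)")
print(f"specificity : {specificity(c):.4f}   (background kept clean)")
print(f"accuracy    : {accuracy(c):.4f}")
print(f"jaccard     : {jaccard(c):.4f}   (= dice / (2 - dice))")

# per-case vs global Dice on a two-volume test set
big_truth = np.ones((10, 10, 10), np.uint8)      # large volume, perfect pred
small_truth = np.ones((2, 2, 2), np.uint8)       # small volume, empty pred
pooled = confusion(big_truth, big_truth) + confusion(np.zeros_like(small_truth), small_truth)
dice_global = 2 * pooled.tp / (2 * pooled.tp + pooled.fp + pooled.fn)
dice_per_case = (1.0 + 0.0) / 2
print(f"\ndice per case = {dice_per_case:.3f}  vs  dice global = {dice_global:.3f}")
print("the big perfect volume dominates the pooled (global) score")
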