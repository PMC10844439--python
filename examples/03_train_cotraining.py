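"""Train the dual-network co-training system on a small phantom split.

Uses a deliberately short schedule so the example finishes in under a
minute; see the ratio-experiment example for a fuller run.
"""

from sdnet import TrainConfig, evaluate, generate_split, train
from sdnet.volume_io import clip_and_normalize

split = generate_split(n_labeled=2, n_unlabeled=8, n_test=2, seed=7)
cfg = TrainConfig(total_iterations=60, width_scale=2, checkpoint_every=0, seed=7)
result = train(split, cfg)

first, last = result.log.iloc[0], result.log.iloc[-1]
print(f"iterations run       : {len(result.log)}")
print(f"vnet dice loss       : {first['vnet_dice']:.3f} -> {last['vnet_dice']:.3f}")
print(f"resvnet dice loss    : {first['resvnet_dice']:.3f} -> {last['resvnet_dice']:.3f}")
print(f"disagreement fraction: {first['dif_fraction']:.3f} -> {last['dif_fraction']:.3f}")
# falling dice losses and a shrinking disagreement region mean both models
# are converging and increasingly agree on voxel labels

share = (result.log["generator"] == "vnet").mean()
print(f"vnet generated pseudo-labels in {share:.0%} of iterations")

test = [(clip_and_normalize(v), m) for v, m in split.test]
report = evaluate(result.models, test)
print(f"test Dice per case   : {report.dice_per_case:.4f}  (mean of per-volume Dice)")
print(f"test Dice global     : {report.dice_global:.4f}  (pooled voxel counts)")
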