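"""Sweep the labeled:unlabeled ("strong:weak") data ratio on phantoms.

Trains one co-training system per ratio on an identically-seeded phantom
pool where only label availability changes; 100:0 is the fully supervised
reference.  Takes a few minutes at these settings.
"""

from sdnet import TrainConfig, run_ratio_experiment

cfg = TrainConfig(total_iterations=100, width_scale=2, checkpoint_every=0)
table = run_ratio_experiment(
    ratios=[(20, 80), (50, 50), (100, 0)],
    base_cfg=cfg,
    seed=7,
    pool_size=10,
    n_test=4,
)
print(table.to_string(index=False))
print("\ndice should tend upward as the labeled share grows; 100:0 bounds it")
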