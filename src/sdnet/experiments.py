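"""Desk-scale experiment harnesses built on the phantom benchmark.

The main harness sweeps the labeled:unlabeled ("strong:weak") ratio: a
fixed pool of phantoms is generated once per seed, then for each ratio only
the label availability changes — the first k volumes keep their masks, the
rest contribute images only.  100:0 is the fully supervised reference.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import pandas as pd

from .cotraining import TrainConfig, train
from .errors import ConfigurationError
from .metrics import evaluate
from .phantoms import PhantomSpec, generate_split
from .volume_io import DatasetSplit, clip_and_normalize

__all__ = ["run_ratio_experiment", "STANDARD_RATIOS"]

STANDARD_RATIOS = ((20, 80), (30, 70), (50, 50), (70, 30), (80, 20), (100, 0))


def _split_with_ratio(full: DatasetSplit, labeled_share: int) -> DatasetSplit:
    """Re-partition a fully-labeled pool so only a share keeps its labels."""
    pool = list(full.labeled)
    n_labeled = round(len(pool) * labeled_share / 100)
    n_labeled = max(1, n_labeled)
    labeled = pool[:n_labeled]
    unlabeled = [v for v, _ in pool[n_labeled:]]
    return DatasetSplit(
        labeled=labeled,
        unlabeled=unlabeled,
        test=full.test,
        manifest={**full.manifest, "labeled_share": labeled_share},
        _unlabeled_truth=[m for _, m in pool[n_labeled:]],
    )


def run_ratio_experiment(
    ratios: Sequence[tuple[int, int]],
    base_cfg: TrainConfig,
    seed: int = 0,
    pool_size: int = 10,
    n_test: int = 4,
    spec: PhantomSpec | None = None,
    warn=None,
) -> pd.DataFrame:
    """Train one co-training run per labeled:unlabeled ratio.

    All ratios share an identically-seeded phantom pool and test set; only
    label availability differs.  Duplicate ratios are deduplicated (with a
    warning via ``warn`` if given).  Returns a frame with columns
    ``ratio, labeled_share, n_labeled, n_unlabeled, dice_per_case,
    dice_global``.
    """
    seen = []
    for r in ratios:
        lab, unl = int(r[0]), int(r[1])
        if lab <= 0:
            raise ConfigurationError(f"ratio {r}: labeled share must be positive")
        if lab + unl != 100:
            raise ConfigurationError(f"ratio {r}: shares must sum to 100")
        if (lab, unl) in seen:
            if warn is not None:
                warn(f"duplicate ratio {lab}:{unl} ignored")
            continue
        seen.append((lab, unl))

    # one shared, fully-labeled pool per seed; ratios only mask labels
    full = generate_split(pool_size, 0, n_test, spec=spec, seed=seed)

    rows = []
    for lab, unl in seen:
        split = _split_with_ratio(full, lab)
        cfg = replace(base_cfg, seed=seed)
        if not split.unlabeled:
            cfg = replace(cfg, batch_unlabeled=0)
        result = train(split, cfg)
        test_norm = [
            (clip_and_normalize(v, cfg.hu_lo, cfg.hu_hi), m) for v, m in split.test
        ]
        report = evaluate(result.models, test_norm)
        rows.append(
            {
                "ratio": f"{lab}:{unl}",
                "labeled_share": lab,
                "n_labeled": len(split.labeled),
                "n_unlabeled": len(split.unlabeled),
                "dice_per_case": report.dice_per_case,
                "dice_global": report.dice_global,
            }
        )
    return pd.DataFrame(rows)
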