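"""Segmentation evaluation: confusion counts, Dice (per case and global),
sensitivity, specificity, accuracy and Jaccard.

Two Dice flavours are reported.  *Dice per case* averages the Dice score
computed on each volume separately; *Dice global* pools the voxel confusion
counts over all volumes first and computes a single Dice — large volumes
dominate it, which is exactly how the two diverge on heterogeneous test
sets.  The remaining ratios are reported on pooled counts (per-case rows
are also available in the report).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbones import BackboneModel, binarize
from .errors import ContractError, EvaluationError, ShapeError
from .volume_io import GroundTruthMask, Volume

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice_score",
    "sensitivity",
    "specificity",
    "accuracy",
    "jaccard",
    "evaluate",
    "predict_fused",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def _as_binary(mask) -> np.ndarray:
    arr = mask.data if isinstance(mask, GroundTruthMask) else np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ContractError("masks must be binary {0,1} grids")
    return arr.astype(bool)


def confusion(pred_mask, truth_mask) -> ConfusionCounts:
    """Exact voxel counts of the four prediction/truth categories."""
    p = _as_binary(pred_mask)
    g = _as_binary(truth_mask)
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    tp = int(np.count_nonzero(p & g))
    tn = int(np.count_nonzero(~p & ~g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float) -> float:
    """A ratio metric; a zero denominator means nothing to get wrong → 1.0."""
    return num / den if den else 1.0


def dice_score(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    c = confusion(mask_a, mask_b)
    return _ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN): fraction of true organ voxels recovered."""
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP): fraction of background kept out of the organ."""
    return _ratio(c.tn, c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total voxels."""
    return _ratio(c.tp + c.tn, c.total)


def jaccard(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); equals Dice/(2 − Dice)."""
    return _ratio(c.tp, c.tp + c.fp + c.fn)


@dataclass
class MetricsReport:
    dice_per_case: float
    dice_global: float
    sensitivity: float
    specificity: float
    accuracy: float
    jaccard: float
    per_volume: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Per-volume rows plus a pooled summary row."""
        rows = [dict(r) for r in self.per_volume]
        rows.append(
            {
                "case": "summary",
                "dice": self.dice_per_case,
                "dice_global": self.dice_global,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "jaccard": self.jaccard,
            }
        )
        return pd.DataFrame(rows)

    def as_dict(self) -> dict[str, float]:
        return {
            "dice_per_case": self.dice_per_case,
            "dice_global": self.dice_global,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "jaccard": self.jaccard,
        }


def predict_fused(models, volume: Volume | np.ndarray, infer: str = "mean") -> np.ndarray:
    """Predicted mask from one model or a cooperating pair.

    ``infer``: ``"mean"`` averages the two organ posteriors before
    binarizing (default for a pair), ``"vnet"``/``"resvnet"`` use a single
    model's output.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if hasattr(models, "forward_probs"):  # a single model of any kind
        models = {getattr(models, "architecture_id", "model"): models}
    elif not isinstance(models, dict):
        models = {m.architecture_id: m for m in models}
    if infer == "mean":
        probs = [m.forward_probs(data).data for m in models.values()]
        fused = np.mean(probs, axis=0)
        return binarize(fused)
    if infer in models:
        return binarize(models[infer].forward_probs(data).data)
    raise ContractError(f"infer={infer!r} not available; models: {list(models)}")


def evaluate(models, test_set, infer: str = "mean") -> MetricsReport:
    """Score a model (or the dual-model pair) on labeled test volumes.

    ``test_set`` is a sequence of ``(Volume, GroundTruthMask)`` pairs with
    volumes already normalized to [0, 1].  Dice per case is the unweighted
    mean of per-volume Dice; every other metric is computed on confusion
    counts pooled over all volumes.
    """
    test_set = list(test_set)
    if not test_set:
        raise EvaluationError("cannot evaluate on an empty test set")
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_volume = []
    dices = []
    for i, (vol, truth) in enumerate(test_set):
        pred = predict_fused(models, vol, infer=infer)
        c = confusion(pred, truth)
        d = dice_score(pred, truth)
        dices.append(d)
        pooled = pooled + c
        per_volume.append(
            {
                "case": i,
                "dice": d,
                "sensitivity": sensitivity(c),
                "specificity": specificity(c),
                "accuracy": accuracy(c),
                "jaccard": jaccard(c),
            }
        )
    return MetricsReport(
        dice_per_case=float(np.mean(dices)),
        dice_global=_ratio(2.0 * pooled.tp, 2.0 * pooled.tp + pooled.fp + pooled.fn),
        sensitivity=sensitivity(pooled),
        specificity=specificity(pooled),
        accuracy=accuracy(pooled),
        jaccard=jaccard(pooled),
        per_volume=per_volume,
    )
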