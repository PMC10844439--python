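"""Training losses: cross-entropy, soft Dice, disagreement MSE, pseudo-label MSE.

All losses take a two-class posterior map (``Tensor`` or array, shape
``(2, D, H, W)``) and return a 0-d :class:`~sdnet.autodiff.Tensor`, so the
same code path serves gradient-based training and plain evaluation
(``float(loss)`` for the value).

Notation: ``g`` is the binary ground truth, ``p`` the predicted posterior
(``p_fg`` its organ channel), ``dif`` the binary disagreement mask between
the two backbones.  The supervised objective is the unweighted sum

    L_s = L_CE + L_Dice + L_MSE^dif

and the unsupervised objective is a voxelwise MSE between the inferior
model's organ posterior and the sharpened soft pseudo-label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, clip_min
from .errors import ConfigurationError, ShapeError
from .volume_io import GroundTruthMask

__all__ = [
    "LOG_EPS",
    "DICE_EPS",
    "LossBundle",
    "cross_entropy_loss",
    "dice_loss",
    "disagreement_mse_loss",
    "weighted_ce_dif_loss",
    "supervised_loss",
    "pseudo_label_mse_loss",
]

LOG_EPS = 1e-7   # lower clamp on probabilities inside log
DICE_EPS = 1e-5  # smoothing term in the soft Dice ratio


def _as_mask_array(truth) -> np.ndarray:
    if isinstance(truth, GroundTruthMask):
        return truth.data
    arr = np.asarray(truth)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ShapeError("ground-truth mask must be binary")
    return arr


def _check_pred(pred, spatial_shape) -> Tensor:
    if hasattr(pred, "foreground"):  # a ProbabilityMap
        pred = pred.data
    pred = as_tensor(pred)
    if pred.shape != (2, *spatial_shape):
        raise ShapeError(
            f"prediction shape {pred.shape} incompatible with truth shape {spatial_shape}"
        )
    return pred


@dataclass
class LossBundle:
    """All loss components of one model on one batch element.

    ``supervised_total = ce + dice + mse_dif`` exactly (unweighted sum);
    ``mse_pseudo`` is present only for the model receiving pseudo-labels.
    Fields hold 0-d Tensors during training; use ``float()`` for values.
    """

    ce: Tensor
    dice: Tensor
    mse_dif: Tensor
    supervised_total: Tensor
    mse_pseudo: Tensor | None = None

    def as_floats(self) -> dict[str, float]:
        out = {
            "ce": float(self.ce),
            "dice": float(self.dice),
            "mse_dif": float(self.mse_dif),
            "supervised_total": float(self.supervised_total),
        }
        out["mse_pseudo"] = float(self.mse_pseudo) if self.mse_pseudo is not None else 0.0
        return out


def cross_entropy_loss(pred, truth) -> Tensor:
    """Mean voxelwise two-class cross-entropy.

    ``-(1/V) Σ_v Σ_c 1[g_v = c] log p_c(v)`` with probabilities clamped
    below at ``LOG_EPS``; nonnegative, ~0 for a one-hot correct prediction.
    """
    g = _as_mask_array(truth)
    pred = _check_pred(pred, g.shape)
    onehot = np.stack([1 - g, g]).astype(np.float64)
    logp = clip_min(pred, LOG_EPS).log()
    return -(logp * onehot).sum() * (1.0 / g.size)


def dice_loss(pred, truth) -> Tensor:
    """Soft Dice loss on the organ channel: 1 − (2Σg·p + ε)/(Σg + Σp + ε)."""
    g = _as_mask_array(truth)
    pred = _check_pred(pred, g.shape)
    p_fg = pred[1]
    inter = (p_fg * g.astype(np.float64)).sum()
    denom = p_fg.sum() + float(g.sum())
    return 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)


def disagreement_mse_loss(pred, truth, dif) -> Tensor:
    """Mean squared error to ground truth, restricted to the disagreement mask.

    The region where the two backbones disagree is re-examined against the
    labels: ``mean_{v: dif_v=1} (g_v − p_fg(v))²``.  Returns 0 when the
    models fully agree (empty mask).
    """
    g = _as_mask_array(truth)
    pred = _check_pred(pred, g.shape)
    dif = np.asarray(dif.data if hasattr(dif, "data") and not isinstance(dif, Tensor) else dif)
    if dif.shape != g.shape:
        raise ShapeError(f"dif shape {dif.shape} != truth shape {g.shape}")
    n_dif = int(dif.sum())
    if n_dif == 0:
        return Tensor(np.float64(0.0))
    diff = pred[1] - g.astype(np.float64)
    return ((diff**2) * dif.astype(np.float64)).sum() * (1.0 / n_dif)


def weighted_ce_dif_loss(pred, truth, dif) -> Tensor:
    """Class-weighted cross-entropy on the disagreement region (ablation).

    Alternative to :func:`disagreement_mse_loss`: voxels in the mask get an
    inverse-class-frequency weighted CE (weights balance organ/background
    counts inside the region), so the scattered minority class is not
    drowned out.  Returns 0 on an empty mask.
    """
    g = _as_mask_array(truth)
    pred = _check_pred(pred, g.shape)
    dif = np.asarray(dif.data if hasattr(dif, "data") and not isinstance(dif, Tensor) else dif)
    n_dif = int(dif.sum())
    if n_dif == 0:
        return Tensor(np.float64(0.0))
    in_dif = dif.astype(bool)
    n_fg = int((g[in_dif] == 1).sum())
    n_bg = n_dif - n_fg
    # balanced weights; a class absent from the region contributes nothing
    w_fg = n_dif / (2.0 * n_fg) if n_fg else 0.0
    w_bg = n_dif / (2.0 * n_bg) if n_bg else 0.0
    weights = np.where(g == 1, w_fg, w_bg) * dif.astype(np.float64)
    onehot = np.stack([1 - g, g]).astype(np.float64)
    logp = clip_min(pred, LOG_EPS).log()
    per_voxel = -(logp * onehot).sum(axis=0)
    return (per_voxel * weights).sum() * (1.0 / n_dif)


def supervised_loss(pred, truth, dif, dif_loss: str = "mse") -> LossBundle:
    """The full supervised objective for one labeled volume.

    ``dif_loss`` selects the disagreement term: ``"mse"`` (default) or
    ``"weighted_ce"`` (the ablation alternative).
    """
    if dif_loss not in ("mse", "weighted_ce"):
        raise ConfigurationError(f"dif_loss must be 'mse' or 'weighted_ce', got {dif_loss!r}")
    ce = cross_entropy_loss(pred, truth)
    dc = dice_loss(pred, truth)
    if dif_loss == "mse":
        md = disagreement_mse_loss(pred, truth, dif)
    else:
        md = weighted_ce_dif_loss(pred, truth, dif)
    return LossBundle(ce=ce, dice=dc, mse_dif=md, supervised_total=ce + dc + md)


def pseudo_label_mse_loss(pred_unlabeled, pseudo) -> Tensor:
    """Unsupervised loss: mean over all voxels of (pseudo − p_fg)².

    ``pseudo`` is the sharpened soft pseudo-label grid in [0, 1] produced by
    the currently-better model; it carries no gradient.
    """
    pl = np.asarray(pseudo.data if hasattr(pseudo, "data") and not isinstance(pseudo, Tensor) else pseudo)
    if pl.min() < 0 or pl.max() > 1:
        raise ShapeError("pseudo-label values must lie in [0, 1]")
    pred = _check_pred(pred_unlabeled, pl.shape)
    diff = pred[1] - pl
    return (diff**2).mean()
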