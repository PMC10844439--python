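"""The co-training engine: disagreement masks, dynamic pseudo-labels, and
the dual-model training loop.

Each iteration draws a batch with equal parts labeled and unlabeled
volumes and routes it through both backbones.  On the labeled part, each
model minimizes cross-entropy + soft Dice, plus an MSE term restricted to
the *disagreement mask* — the voxels where the two models' binarized
predictions differ, i.e. where at least one of them must be wrong.  On the
unlabeled part, the model with the smaller labeled Dice loss (the
currently-better model, re-selected every iteration) produces soft
pseudo-labels, sharpened by a temperature transform, for the other model;
pseudo-labels are constants — no gradient reaches their generator.  The
two models' parameters are updated independently by momentum SGD under a
step-decay learning-rate schedule.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import SGD, Tensor
from .backbones import BackboneModel, binarize, build_backbone
from .errors import ConfigurationError, ShapeError, TrainingError
from .losses import LossBundle, pseudo_label_mse_loss, supervised_loss
from .volume_io import DatasetSplit, augment, clip_and_normalize

__all__ = [
    "DisagreementMask",
    "PseudoLabel",
    "TrainConfig",
    "TrainResult",
    "StepResult",
    "difference_mask",
    "sharpen",
    "select_generator",
    "learning_rate",
    "train_step",
    "train",
]

MODEL_IDS = ("vnet", "resvnet")


@dataclass
class DisagreementMask:
    """Binary grid: 1 where the two backbones' binarized predictions differ."""

    data: np.ndarray

    @property
    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class PseudoLabel:
    """Soft foreground target in [0, 1] produced by the better model."""

    data: np.ndarray
    generator_id: str
    temperature: float


@dataclass
class TrainConfig:
    """Hyperparameters of the co-training loop.

    Defaults follow the reference schedule: SGD with momentum 0.9 and
    weight decay 1e-4; initial learning rate 0.01 divided by 10 every 200
    iterations for 1200 iterations; batches of 4 volumes, 2 labeled and 2
    unlabeled.  ``sharpen_T`` is the pseudo-label temperature (T=1 leaves
    probabilities unchanged; smaller T pushes them toward 0/1).
    """

    total_iterations: int = 1200
    lr0: float = 0.01
    lr_decay_every: int = 200
    lr_decay_factor: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_labeled: int = 2
    batch_unlabeled: int = 2
    sharpen_T: float = 0.5
    seed: int = 0
    checkpoint_every: int = 200
    # model / preprocessing knobs
    width_scale: int = 4
    depth: int = 3
    hu_lo: float = 0.0
    hu_hi: float = 400.0
    augment: bool = True
    dif_loss: str = "mse"       # or "weighted_ce" (ablation)
    unsup_weight: float = 1.0
    mutual: bool = False        # symmetric pseudo-label exchange (experimental)

    def validate(self) -> None:
        if self.total_iterations < 0:
            raise ConfigurationError("total_iterations must be >= 0")
        if self.lr0 <= 0 or self.lr_decay_factor <= 0:
            raise ConfigurationError("lr0 and lr_decay_factor must be positive")
        if self.lr_decay_every <= 0:
            raise ConfigurationError("lr_decay_every must be >= 1")
        if self.batch_labeled < 1:
            raise ConfigurationError("batch_labeled must be >= 1")
        if self.batch_unlabeled < 0:
            raise ConfigurationError("batch_unlabeled must be >= 0")
        if self.sharpen_T <= 0:
            raise ConfigurationError(f"sharpen_T must be > 0, got {self.sharpen_T}")
        if self.dif_loss not in ("mse", "weighted_ce"):
            raise ConfigurationError(f"dif_loss must be 'mse' or 'weighted_ce'")
        if not self.hu_lo < self.hu_hi:
            raise ConfigurationError("hu_lo must be < hu_hi")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in dc_fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown config fields: {sorted(bad)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class StepResult:
    bundles: dict[str, LossBundle]
    generator_id: str | None
    dif_fraction: float
    lr: float


@dataclass
class TrainResult:
    models: dict[str, BackboneModel]
    log: pd.DataFrame
    val_log: pd.DataFrame
    checkpoints: list[Path] = field(default_factory=list)


# --------------------------------------------------------------------------
# primitives


def difference_mask(p1, p2) -> DisagreementMask:
    """Voxelwise XOR of the two binarized predictions (the uncertain region)."""
    b1, b2 = binarize(_probs_data(p1)), binarize(_probs_data(p2))
    if b1.shape != b2.shape:
        raise ShapeError(f"shape mismatch: {b1.shape} vs {b2.shape}")
    return DisagreementMask((b1 ^ b2).astype(np.uint8))


def _probs_data(p) -> np.ndarray:
    if isinstance(p, Tensor):
        return p.data
    if hasattr(p, "data"):
        return np.asarray(p.data)
    return np.asarray(p)


def sharpen(p: np.ndarray, T: float) -> np.ndarray:
    """Temperature sharpening: p^(1/T) / (p^(1/T) + (1−p)^(1/T)).

    T=1 is the identity; T→0 approaches hard thresholding at 0.5 (exactly
    0.5 stays 0.5).  Computed via the odds ratio for stability at extreme
    temperatures.
    """
    if T <= 0:
        raise ConfigurationError(f"sharpening temperature must be > 0, got {T}")
    p = np.asarray(p, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ShapeError("probabilities must lie in [0, 1]")
    if T == 1.0:
        return p.copy()
    with np.errstate(divide="ignore", over="ignore"):
        odds = (1.0 - p) / p            # inf at p=0 → sharpened 0
        s = 1.0 / (1.0 + odds ** (1.0 / T))
    return s


def select_generator(loss_vnet: float, loss_resvnet: float) -> str:
    """The model with the strictly smaller labeled Dice loss generates
    pseudo-labels; an exact tie goes to ``vnet`` (fixed, documented rule)."""
    lv, lr = float(loss_vnet), float(loss_resvnet)
    if not (np.isfinite(lv) and np.isfinite(lr)):
        raise FloatingPointError(f"non-finite Dice losses: {lv}, {lr}")
    return "vnet" if lv <= lr else "resvnet"


def learning_rate(iteration: int, cfg: TrainConfig) -> float:
    """Step decay: lr0 · factor^floor(iteration / decay_every)."""
    if iteration < 0:
        raise ConfigurationError("iteration must be >= 0")
    return cfg.lr0 * cfg.lr_decay_factor ** (iteration // cfg.lr_decay_every)


# --------------------------------------------------------------------------
# one training step


def _volume_data(v) -> np.ndarray:
    return v.data if hasattr(v, "data") else np.asarray(v)


def _config_hash(cfg: TrainConfig) -> str:
    import hashlib
    import json

    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def train_step(
    models: dict[str, BackboneModel],
    labeled: list[tuple],
    unlabeled: list,
    cfg: TrainConfig,
    iteration: int = 0,
    optimizers: dict[str, SGD] | None = None,
) -> StepResult:
    """One co-training iteration on an already-normalized batch.

    ``models`` maps ``"vnet"``/``"resvnet"`` to any object exposing
    ``forward_probs(data) -> Tensor``; ``labeled`` holds (volume, mask)
    pairs and ``unlabeled`` holds volumes.  With ``optimizers`` supplied,
    both models are updated independently at the scheduled learning rate;
    without, the step only computes losses (useful for frozen-model
    analysis).
    """
    if set(models) != set(MODEL_IDS):
        raise ConfigurationError(f"models must be keyed {MODEL_IDS}, got {sorted(models)}")
    if not labeled:
        raise TrainingError("training requires at least one labeled volume per step")

    # Eqs. of the routing contract: both models predict the full batch and
    # the outputs are partitioned into labeled and unlabeled parts.
    preds_lab = {
        mid: [models[mid].forward_probs(_volume_data(v)) for v, _ in labeled]
        for mid in MODEL_IDS
    }
    preds_unl = {
        mid: [models[mid].forward_probs(_volume_data(v)) for v in unlabeled]
        for mid in MODEL_IDS
    }

    # shared disagreement mask per labeled volume
    difs = [
        difference_mask(preds_lab["vnet"][j], preds_lab["resvnet"][j])
        for j in range(len(labeled))
    ]
    dif_fraction = float(np.mean([d.data.mean() for d in difs]))

    # supervised objective per model, averaged over the labeled part
    bundles: dict[str, LossBundle] = {}
    for mid in MODEL_IDS:
        parts = [
            supervised_loss(preds_lab[mid][j], labeled[j][1], difs[j], dif_loss=cfg.dif_loss)
            for j in range(len(labeled))
        ]
        n = len(parts)
        ce = sum((b.ce for b in parts), Tensor(0.0)) * (1.0 / n)
        dc = sum((b.dice for b in parts), Tensor(0.0)) * (1.0 / n)
        md = sum((b.mse_dif for b in parts), Tensor(0.0)) * (1.0 / n)
        bundles[mid] = LossBundle(ce=ce, dice=dc, mse_dif=md, supervised_total=ce + dc + md)

    # dynamic pseudo-label generation on the unlabeled part
    generator_id = None
    totals = {mid: bundles[mid].supervised_total for mid in MODEL_IDS}
    if unlabeled and cfg.unsup_weight > 0:
        generator_id = select_generator(
            float(bundles["vnet"].dice), float(bundles["resvnet"].dice)
        )
        receivers = [mid for mid in MODEL_IDS if mid != generator_id]
        if cfg.mutual:
            receivers = list(MODEL_IDS)
        for mid in receivers:
            other = "vnet" if mid == "resvnet" else "resvnet"
            # pseudo-labels are detached: constants w.r.t. the generator
            mse_terms = []
            for k in range(len(unlabeled)):
                pl = PseudoLabel(
                    data=sharpen(preds_unl[other][k].data[1], cfg.sharpen_T),
                    generator_id=other,
                    temperature=cfg.sharpen_T,
                )
                mse_terms.append(pseudo_label_mse_loss(preds_unl[mid][k], pl))
            mse_pseudo = sum(mse_terms, Tensor(0.0)) * (1.0 / len(mse_terms))
            bundles[mid].mse_pseudo = mse_pseudo
            totals[mid] = totals[mid] + cfg.unsup_weight * mse_pseudo

    lr = learning_rate(iteration, cfg)
    if optimizers is not None:
        for mid in MODEL_IDS:
            opt = optimizers[mid]
            opt.lr = lr
            opt.zero_grad()
            totals[mid].backward()
            opt.step()
            opt.zero_grad()

    return StepResult(bundles=bundles, generator_id=generator_id,
                      dif_fraction=dif_fraction, lr=lr)


# --------------------------------------------------------------------------
# the full loop


def _normalize_split(split: DatasetSplit, cfg: TrainConfig):
    lab = [(clip_and_normalize(v, cfg.hu_lo, cfg.hu_hi), m) for v, m in split.labeled]
    unl = [clip_and_normalize(v, cfg.hu_lo, cfg.hu_hi) for v in split.unlabeled]
    return lab, unl


def train(
    split: DatasetSplit,
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
    val_set: list[tuple] | None = None,
    models: dict[str, BackboneModel] | None = None,
) -> TrainResult:
    """Train the cooperating pair on a dataset split.

    Volumes are HU-clipped and normalized up front; each iteration samples
    (with replacement) ``batch_labeled`` labeled and ``batch_unlabeled``
    unlabeled volumes, applies random flip/rotation augmentation to the
    labeled pairs, and runs :func:`train_step`.  An empty unlabeled set
    falls back to purely supervised co-training.  Checkpoints (both models,
    optimizer state, iteration) are written every ``checkpoint_every``
    iterations when ``out_dir`` is given.
    """
    cfg.validate()
    if not split.labeled:
        raise TrainingError("the labeled set is empty; co-training needs labels")

    labeled, unlabeled = _normalize_split(split, cfg)
    if val_set is not None:
        val_set = [(clip_and_normalize(v, cfg.hu_lo, cfg.hu_hi), m) for v, m in val_set]

    # separate streams for the labeled and unlabeled pipelines: a
    # supervised-only run (batch_unlabeled=0) with the same seed then sees
    # the identical sequence of labeled batches and augmentations, so
    # semi-supervised vs supervised comparisons are paired in all
    # exogenous randomness
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(6)
    rng_lab_sample = np.random.default_rng(child[0])
    rng_lab_augment = np.random.default_rng(child[1])
    rng_unl_sample = np.random.default_rng(child[2])
    rng_unl_augment = np.random.default_rng(child[3])
    seed_vnet = int(child[4].generate_state(1)[0] % (2**31))
    seed_resvnet = int(child[5].generate_state(1)[0] % (2**31))

    if models is None:
        models = {
            "vnet": build_backbone("vnet", cfg.width_scale, cfg.depth, seed_vnet),
            "resvnet": build_backbone("resvnet", cfg.width_scale, cfg.depth, seed_resvnet),
        }
    optimizers = {
        mid: SGD(models[mid].parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
        for mid in MODEL_IDS
    }

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    val_rows: list[dict] = []
    checkpoints: list[Path] = []
    n_unl_batch = cfg.batch_unlabeled if unlabeled else 0

    for it in range(cfg.total_iterations):
        idx_l = rng_lab_sample.integers(0, len(labeled), size=cfg.batch_labeled)
        batch_l = []
        for i in idx_l:
            vol, mask = labeled[int(i)]
            if cfg.augment:
                vol, mask, _ = augment(vol, mask, rng_lab_augment)
            batch_l.append((vol, mask))
        batch_u = []
        if n_unl_batch:
            idx_u = rng_unl_sample.integers(0, len(unlabeled), size=n_unl_batch)
            for i in idx_u:
                vol = unlabeled[int(i)]
                if cfg.augment:
                    vol, _, _ = augment(vol, None, rng_unl_augment)
                batch_u.append(vol)

        t0 = time.perf_counter()
        step = train_step(models, batch_l, batch_u, cfg, it, optimizers)
        row = {"iteration": it, "lr": step.lr, "generator": step.generator_id or "",
               "dif_fraction": step.dif_fraction,
               "step_seconds": time.perf_counter() - t0}
        for mid in MODEL_IDS:
            for key, val in step.bundles[mid].as_floats().items():
                row[f"{mid}_{key}"] = val
        rows.append(row)

        if cfg.checkpoint_every and (it + 1) % cfg.checkpoint_every == 0:
            if val_set:
                from .metrics import evaluate  # local import: avoids cycle

                report = evaluate(models, val_set)
                val_rows.append({"iteration": it + 1, **report.as_dict()})
            if out_path is not None:
                ck = out_path / f"checkpoint_{it + 1:06d}.npz"
                payload = {"iteration": np.int64(it + 1),
                           "config_hash": np.bytes_(_config_hash(cfg))}
                for mid in MODEL_IDS:
                    for k, v in models[mid].state_dict().items():
                        payload[f"{mid}_{k}"] = v
                    for j, v in enumerate(optimizers[mid]._velocity):
                        payload[f"opt.{mid}.v{j}"] = v
                np.savez(ck, **payload)
                checkpoints.append(ck)

    log = pd.DataFrame(rows)
    if out_path is not None and len(log):
        log.to_csv(out_path / "training_log.csv", index=False)
    return TrainResult(models=models, log=log, val_log=pd.DataFrame(val_rows),
                       checkpoints=checkpoints)


def load_checkpoint(path, width_scale: int = 4, depth: int = 3) -> dict[str, BackboneModel]:
    """Rebuild both models from a ``.npz`` checkpoint written by :func:`train`."""
    with np.load(path) as data:
        models = {}
        for mid in MODEL_IDS:
            model = build_backbone(mid, width_scale, depth, seed=0)
            state = {
                k[len(mid) + 1 :]: data[k] for k in data.files if k.startswith(mid + "_")
            }
            model.load_state_dict(state)
            models[mid] = model
    return models
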