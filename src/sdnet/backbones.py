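"""The two cooperating segmentation backbones: V-Net and 3D-ResV-Net.

Both are 3D encoder–decoder networks with a shared contract: input a
normalized volume, output per-voxel two-class posteriors (background /
liver) of the same spatial shape.  The residual twin wraps every stage's
convolutional block with an additive identity (or 1x1x1 projection)
shortcut — the two architectures are otherwise identical, which is what
makes their disagreement informative rather than systematic.

Desk-scale design: 3x3x3 convolutions, instance normalization, leaky ReLU,
average-pool downsampling and nearest-neighbour upsampling with encoder
skip concatenation.  Width and depth are tiny by default (width_scale=4,
depth=3) so the whole framework trains in seconds on a CPU; both are plain
config knobs for larger runs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ShapeError
from .volume_io import Volume

__all__ = ["BackboneModel", "ProbabilityMap", "build_backbone", "predict", "binarize"]

ARCHITECTURES = ("vnet", "resvnet")


class ProbabilityMap:
    """Per-voxel class posteriors, shape (2, D, H, W); channel 1 = organ."""

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray):
        data = np.asarray(data)
        if data.ndim != 4 or data.shape[0] != 2:
            raise ShapeError(f"probability map must be (2, D, H, W), got {data.shape}")
        sums = data.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-5 or data.min() < 0:
            raise ShapeError("probability map is not voxelwise normalized")
        self.data = data

    @property
    def foreground(self) -> np.ndarray:
        return self.data[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]


def binarize(p: ProbabilityMap | np.ndarray) -> np.ndarray:
    """Argmax over the two classes; exact ties go to background (class 0)."""
    data = p.data if isinstance(p, ProbabilityMap) else np.asarray(p)
    return (data[1] > data[0]).astype(np.uint8)


# --------------------------------------------------------------------------
# layers


class _InstanceNorm:
    """Per-channel, per-sample normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta, self.eps)

    def parameters(self):
        return [self.gamma, self.beta]


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]


class _Block:
    """conv(3³) → IN → LReLU, optionally with an additive residual shortcut."""

    def __init__(self, c_in: int, c_out: int, rng, residual: bool):
        self.conv = _Conv(c_in, c_out, 3, rng)
        self.norm = _InstanceNorm(c_out)
        self.residual = residual
        self.proj = None
        if residual and c_in != c_out:
            self.proj = _Conv(c_in, c_out, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        if self.residual:
            shortcut = self.proj(x) if self.proj is not None else x
            y = y + shortcut
        return ad.leaky_relu(y)

    def parameters(self):
        ps = self.conv.parameters() + self.norm.parameters()
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps


class BackboneModel:
    """An encoder–decoder segmentation network with a two-class softmax head."""

    def __init__(self, architecture_id: str, width_scale: int = 4, depth: int = 3,
                 seed: int = 0):
        if architecture_id not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture_id {architecture_id!r}; choose from {ARCHITECTURES}"
            )
        if depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {depth}")
        if width_scale < 2:
            raise ConfigurationError(f"width_scale must be >= 2, got {width_scale}")
        self.architecture_id = architecture_id
        self.width_scale = int(width_scale)
        self.depth = int(depth)
        self.rng_seed = int(seed)
        residual = architecture_id == "resvnet"
        rng = np.random.default_rng(seed)

        widths = [width_scale * 2**i for i in range(depth)]
        self.encoder = [_Block(1 if i == 0 else widths[i - 1], widths[i], rng, residual)
                        for i in range(depth)]
        # decoder level i fuses upsampled deep features with the encoder skip
        self.decoder = [
            _Block(widths[i + 1] + widths[i], widths[i], rng, residual)
            for i in reversed(range(depth - 1))
        ]
        self.head = _Conv(widths[0], 2, 1, rng)

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for block in self.encoder + self.decoder:
            ps += block.parameters()
        ps += self.head.parameters()
        return ps

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ConfigurationError(
                f"checkpoint has {len(state)} arrays, model needs {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ConfigurationError(f"checkpoint shape mismatch at p{i}")
            p.data = arr.astype(p.data.dtype)

    # -- forward ---------------------------------------------------------
    def _check_input(self, shape: Sequence[int]) -> None:
        div = 2 ** (self.depth - 1)
        if any(s % div for s in shape):
            raise ShapeError(
                f"spatial dims {tuple(shape)} must be divisible by 2**(depth-1)={div}"
            )

    def forward_probs(self, volume_data: np.ndarray) -> Tensor:
        """One volume (D, H, W) in [0, 1] → softmax posteriors Tensor (2, D, H, W)."""
        volume_data = np.asarray(volume_data)
        self._check_input(volume_data.shape)
        x = Tensor(volume_data.astype(np.float32)[None, None])
        skips = []
        for i, block in enumerate(self.encoder):
            x = block(x)
            if i < self.depth - 1:
                skips.append(x)
                x = ad.avg_pool3d(x, 2)
        for block, skip in zip(self.decoder, reversed(skips)):
            x = ad.upsample_nearest3d(x, 2)
            x = block(ad.concat([x, skip], axis=1))
        logits = self.head(x)
        probs = ad.softmax(logits, axis=1)
        return probs.reshape(2, *volume_data.shape)

    def __call__(self, volume_data: np.ndarray) -> Tensor:
        return self.forward_probs(volume_data)


def build_backbone(architecture_id: str, width_scale: int = 4, depth: int = 3,
                   seed: int = 0) -> BackboneModel:
    """Construct a backbone with reproducible initialization.

    Two calls with identical arguments give models whose forward passes are
    bit-identical on any fixed input.
    """
    return BackboneModel(architecture_id, width_scale, depth, seed)


def predict(
    model: BackboneModel,
    volumes: Sequence[Volume | np.ndarray],
    n_labeled: int | None = None,
):
    """Run inference on a batch of normalized volumes.

    Returns a list of :class:`ProbabilityMap`, one per input.  When
    ``n_labeled`` is given, the list is partitioned into
    ``(labeled_maps, unlabeled_maps)`` matching the batch composition —
    labeled volumes first, exactly as they were routed in.
    """
    maps = []
    for v in volumes:
        data = v.data if isinstance(v, Volume) else np.asarray(v)
        probs = model.forward_probs(data)
        maps.append(ProbabilityMap(probs.data.astype(np.float64)))
    if n_labeled is None:
        return maps
    if not 0 <= n_labeled <= len(maps):
        raise ShapeError(f"n_labeled={n_labeled} out of range for batch of {len(maps)}")
    return maps[:n_labeled], maps[n_labeled:]
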