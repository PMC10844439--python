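"""Volumes, masks, NIfTI I/O, CT preprocessing and train-time augmentation.

The geometric conventions used throughout the package live here: grids are
3D, indexed ``(z, y, x)``, 0-based.  Spacing and affine metadata are carried
through reads and writes but no operation resamples or reorients — the
segmentation math is purely voxel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import nibabel as nib
import numpy as np

from .errors import ConfigurationError, NonBinaryMaskError, NotAVolumeError, ShapeError

__all__ = [
    "Volume",
    "GroundTruthMask",
    "DatasetSplit",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "clip_and_normalize",
    "augment",
    "apply_transform",
]

# Default CT intensity window: clip to [0, 400] HU before normalizing.
DEFAULT_HU_RANGE = (0.0, 400.0)


@dataclass
class Volume:
    """A 3D scalar image: HU before preprocessing, [0, 1] after.

    ``spacing`` (mm) and ``affine`` are pass-through metadata; none of the
    losses or metrics depend on them.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotAVolumeError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class GroundTruthMask:
    """A binary 3D grid aligned with its Volume (1 = organ)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotAVolumeError(f"expected a 3D mask, got ndim={self.data.ndim}")
        values = np.unique(self.data)
        if not np.isin(values, (0, 1)).all():
            raise NonBinaryMaskError(f"mask values outside {{0,1}}: {values[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class DatasetSplit:
    """Labeled pairs, unlabeled volumes, and a held-out test set.

    Masks of the unlabeled samples are kept in ``_unlabeled_truth`` for
    evaluation and experiments only; the trainer never sees them.
    """

    labeled: list[tuple[Volume, GroundTruthMask]]
    unlabeled: list[Volume]
    test: list[tuple[Volume, GroundTruthMask]]
    manifest: dict = field(default_factory=dict)
    _unlabeled_truth: list[GroundTruthMask] | None = None


# --------------------------------------------------------------------------
# NIfTI I/O


def _load(path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NotAVolumeError(f"{path} holds a {data.ndim}D image, expected 3D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), spacing


def read_volume(path) -> Volume:
    """Read a 3D NIfTI image as a Volume (float64 data)."""
    data, affine, spacing = _load(path)
    return Volume(data.astype(np.float64), spacing, affine)


def read_mask(path) -> GroundTruthMask:
    """Read a 3D NIfTI label image; values must be exactly {0, 1}."""
    data, affine, spacing = _load(path)
    return GroundTruthMask(data, spacing, affine)  # validates binarity


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: GroundTruthMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Preprocessing


def clip_and_normalize(volume: Volume, lo: float = DEFAULT_HU_RANGE[0],
                       hi: float = DEFAULT_HU_RANGE[1]) -> Volume:
    """Clamp intensities to [lo, hi] HU and rescale linearly to [0, 1].

    The default window keeps the soft-tissue range relevant for liver CT and
    discards irrelevant extremes.  Monotone nondecreasing and idempotent on
    already-normalized data with ``(lo, hi) = (0, 1)``.
    """
    if not lo < hi:
        raise ConfigurationError(f"clip range requires lo < hi, got lo={lo}, hi={hi}")
    out = (np.clip(volume.data, lo, hi) - lo) / (hi - lo)
    return replace(volume, data=out)


# --------------------------------------------------------------------------
# Augmentation: axis flips and 90-degree in-plane rotations.  Restricting to
# exact grid symmetries keeps masks strictly binary (no interpolation) and
# makes every transform invertible.

_PLANES = ((0, 1), (0, 2), (1, 2))


def apply_transform(data: np.ndarray, transform: dict) -> np.ndarray:
    """Apply a recorded flip/rotation transform to a 3D grid."""
    out = data
    for axis, do_flip in enumerate(transform["flips"]):
        if do_flip:
            out = np.flip(out, axis=axis)
    k = transform["rot_k"]
    if k:
        out = np.rot90(out, k=k, axes=_PLANES[transform["rot_plane"]])
    return np.ascontiguousarray(out)


def invert_transform(data: np.ndarray, transform: dict) -> np.ndarray:
    """Undo :func:`apply_transform`."""
    out = data
    k = transform["rot_k"]
    if k:
        out = np.rot90(out, k=-k, axes=_PLANES[transform["rot_plane"]])
    for axis in reversed(range(3)):
        if transform["flips"][axis]:
            out = np.flip(out, axis=axis)
    return np.ascontiguousarray(out)


def augment(
    volume: Volume,
    mask: GroundTruthMask | None,
    rng: np.random.Generator,
) -> tuple[Volume, GroundTruthMask | None, dict]:
    """Random flip + 90° rotation, identical on volume and mask.

    Rotations only act in axis-aligned planes of equal extent, so arbitrary
    (non-cubic) grids keep their shape.  Returns the transformed pair and the
    transform record (``flips``, ``rot_plane``, ``rot_k``).
    """
    if mask is not None and mask.data.shape != volume.data.shape:
        raise ShapeError(
            f"volume shape {volume.data.shape} != mask shape {mask.data.shape}"
        )
    flips = [bool(rng.integers(2)) for _ in range(3)]
    shape = volume.data.shape
    square = [i for i, (a, b) in enumerate(_PLANES) if shape[a] == shape[b]]
    if square:
        rot_plane = int(rng.choice(square))
        rot_k = int(rng.integers(4))
    else:
        rot_plane, rot_k = 0, 0
    transform = {"flips": flips, "rot_plane": rot_plane, "rot_k": rot_k}
    new_vol = replace(volume, data=apply_transform(volume.data, transform))
    new_mask = None
    if mask is not None:
        new_mask = replace(mask, data=apply_transform(mask.data, transform))
    return new_vol, new_mask, transform
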