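"""Synthetic CT phantoms with ground-truth organ masks.

The generator emulates the structure that makes contrast CT liver
segmentation hard at desk scale: one large, smooth, lobed foreground organ;
nearby *iso-intense* distractor blobs (spleen/stomach/kidney stand-ins that
cannot be separated by thresholding); partial-volume edge blur; and additive
acquisition noise.  The mask is always the exact pre-blur organ indicator,
so ground truth is never corrupted by the imaging model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .volume_io import DatasetSplit, GroundTruthMask, Volume

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_split"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic abdominal-CT-like volume.

    Intensities are Hounsfield units.  Defaults give a liver-like organ
    (~110 HU, contrast-enhanced) on a soft-tissue background (~20 HU) with
    iso-intense distractors, ~1-voxel partial-volume blur and 25 HU noise —
    deliberately hard enough that intensity thresholding and tiny labeled
    sets both fall short of ceiling performance.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    organ_axes: tuple[float, float, float] = (11.0, 9.0, 8.0)
    organ_center_jitter: float = 3.5
    lobe_count: int = 4
    distractor_count: int = 4
    organ_hu: float = 110.0
    background_hu: float = 20.0
    distractor_hu: float = 110.0
    edge_blur_sigma: float = 1.2
    noise_sd: float = 25.0
    # per-sample heterogeneity (seed-driven), emulating patient/scanner
    # variability: each sample scales its organ semi-axes by ±shape_jitter
    # and its organ/distractor contrast over background by ±contrast_jitter
    shape_jitter: float = 0.22
    contrast_jitter: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 ints >= 8, got {self.grid_shape}")
        if len(self.organ_axes) != 3 or any(a <= 0 for a in self.organ_axes):
            raise ConfigurationError(f"organ_axes must be positive, got {self.organ_axes}")
        for a, s in zip(self.organ_axes, self.grid_shape):
            if a * (1 + self.shape_jitter) >= s / 2:
                raise ConfigurationError(
                    f"organ_axes: semi-axis {a} (with shape_jitter) >= half grid extent {s / 2}"
                )
        if not 0 <= self.shape_jitter < 1:
            raise ConfigurationError("shape_jitter must be in [0, 1)")
        if not 0 <= self.contrast_jitter < 1:
            raise ConfigurationError("contrast_jitter must be in [0, 1)")
        if self.organ_center_jitter < 0:
            raise ConfigurationError("organ_center_jitter must be >= 0")
        if self.lobe_count < 0:
            raise ConfigurationError("lobe_count must be >= 0")
        if self.distractor_count < 0:
            raise ConfigurationError("distractor_count must be >= 0")
        if self.edge_blur_sigma < 0:
            raise ConfigurationError("edge_blur_sigma must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class PhantomSample:
    """A generated volume, its exact mask, and the provenance record."""

    volume: Volume
    mask: GroundTruthMask
    meta: dict = field(default_factory=dict)


def _ellipsoid(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return q <= radius**2


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom; identical (spec, seed) pairs are bit-identical.

    The organ is an ellipsoid deformed by ``lobe_count`` spherical bumps
    centred on its surface (smooth liver-like non-convexity).  Distractors
    are iso-intense spheres rejection-sampled at least 2 voxels away from
    the organ, so they never touch or overwrite organ voxels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)

    center = np.array(shape) / 2.0 - 0.5
    if spec.organ_center_jitter > 0:
        center = center + rng.uniform(
            -spec.organ_center_jitter, spec.organ_center_jitter, size=3
        )
    axes = np.asarray(spec.organ_axes, dtype=float)
    if spec.shape_jitter > 0:
        # fixed draw order: the scale factors depend on the seed only, so
        # growing organ_axes still grows the organ (monotonicity)
        axes = axes * rng.uniform(1 - spec.shape_jitter, 1 + spec.shape_jitter, size=3)

    mask = _ellipsoid(shape, center, axes)
    for _ in range(spec.lobe_count):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = 1.0 / np.sqrt(np.sum((direction / axes) ** 2))  # ray-ellipsoid hit
        surface_pt = center + direction * t
        radius = rng.uniform(0.3, 0.55) * float(axes.min())
        bump = _sphere(shape, surface_pt, radius)
        mask = mask | bump

    # distractors: same HU as the organ, abutting it (2-5 voxels away) so
    # the partial-volume blur merges their boundary zones with the organ's —
    # rejecting them needs shape context, not intensity
    dist_from_organ = ndimage.distance_transform_edt(~mask)
    distractors = np.zeros(shape, dtype=bool)
    placed = 0
    attempts = 0
    while placed < spec.distractor_count and attempts < 500 * max(spec.distractor_count, 1):
        attempts += 1
        c = rng.uniform(2, np.array(shape) - 3)
        r_lo, r_hi = 2.0, 0.55 * float(axes.min())
        if r_hi <= r_lo:  # small organs get proportionally small distractors
            r_lo, r_hi = 0.4 * float(axes.min()), 0.7 * float(axes.min())
        r = rng.uniform(r_lo, r_hi)
        blob = _sphere(shape, c, r)
        if not blob.any():
            continue
        gap = dist_from_organ[blob].min()
        if 2.0 <= gap <= 5.0:
            distractors |= blob
            placed += 1

    # independent contrast factors for organ and distractors: intensity
    # alone cannot identify the organ across samples
    organ_hu, distractor_hu = spec.organ_hu, spec.distractor_hu
    if spec.contrast_jitter > 0:
        f_organ = rng.uniform(1 - spec.contrast_jitter, 1 + spec.contrast_jitter)
        f_dist = rng.uniform(1 - spec.contrast_jitter, 1 + spec.contrast_jitter)
        organ_hu = spec.background_hu + (organ_hu - spec.background_hu) * f_organ
        distractor_hu = spec.background_hu + (distractor_hu - spec.background_hu) * f_dist

    template = np.full(shape, spec.background_hu, dtype=np.float64)
    template[distractors] = distractor_hu
    template[mask] = organ_hu  # organ takes precedence by construction

    intensity = template
    if spec.edge_blur_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.edge_blur_sigma)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)

    return PhantomSample(
        volume=Volume(intensity.astype(np.float64)),
        mask=GroundTruthMask(mask.astype(np.uint8)),
        meta={"spec": spec, "seed": spec.seed, "distractors_placed": placed},
    )


def _sample_seed(master_seed: int, index: int) -> int:
    """Counter-based per-sample seed: stable under growing the split."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_split(
    n_labeled: int,
    n_unlabeled: int,
    n_test: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> DatasetSplit:
    """Generate a labeled/unlabeled/test split of independent phantoms.

    Per-sample seeds are derived from ``(seed, index)`` with a counter-based
    scheme, so enlarging any partition never changes earlier samples.  The
    unlabeled samples keep their masks internally (for evaluation only); the
    split hands the trainer their volumes alone.
    """
    if min(n_labeled, n_unlabeled, n_test) < 0:
        raise ConfigurationError("split counts must be >= 0")
    spec = spec if spec is not None else PhantomSpec()
    spec.validate()

    samples = []
    total = n_labeled + n_unlabeled + n_test
    for i in range(total):
        samples.append(generate_phantom(replace(spec, seed=_sample_seed(seed, i))))

    labeled = [(s.volume, s.mask) for s in samples[:n_labeled]]
    unlabeled_samples = samples[n_labeled : n_labeled + n_unlabeled]
    test = [(s.volume, s.mask) for s in samples[n_labeled + n_unlabeled :]]
    manifest = {
        "seed": int(seed),
        "n_labeled": int(n_labeled),
        "n_unlabeled": int(n_unlabeled),
        "n_test": int(n_test),
        "sample_seeds": [s.meta["seed"] for s in samples],
    }
    return DatasetSplit(
        labeled=labeled,
        unlabeled=[s.volume for s in unlabeled_samples],
        test=test,
        manifest=manifest,
        _unlabeled_truth=[s.mask for s in unlabeled_samples],
    )
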