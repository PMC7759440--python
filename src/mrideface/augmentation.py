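"""Random volumetric augmentation applied identically to image and labels.

Seven transforms are sampled independently per draw: additive Gaussian
noise, rotation of -15 to +15 degrees about each axis, random axis flips,
random axis transposition, per-axis shifts of 0 to 0.10 of the axis extent,
per-axis shears with coefficient 0 to 0.20, and isotropic resizing by a
factor of 0.90 to 1.10.  Geometric transforms share one set of sampled
parameters for the volume and its label map; intensities are interpolated
linearly and labels by nearest neighbour, so label codes are never invented.

Composition order: transpose -> flips -> one combined affine resampling
(rotate, shear, scale, shift) -> additive noise.  A single resampling keeps
interpolation blur minimal, and noise is added last so it is not smoothed.
Out-of-field voxels are filled with 0 (air).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import Volume
from .phantom import LabelMap


@dataclass
class AugmentSpec:
    """Sampling ranges for one augmentation draw (defaults = full protocol)."""

    gaussian_noise_sigma: tuple[float, float] = (0.0, 0.02)  # fraction of p99 intensity
    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    flip_prob: float = 0.5
    transpose: bool = True
    shift_frac: tuple[float, float] = (0.0, 0.10)
    shear_frac: tuple[float, float] = (0.0, 0.20)
    resize_factor: tuple[float, float] = (0.90, 1.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        for lo, hi in (self.gaussian_noise_sigma, self.rotation_deg,
                       self.shift_frac, self.shear_frac, self.resize_factor):
            if lo > hi:
                raise ValueError("range bounds must satisfy lo <= hi")

    @classmethod
    def identity(cls) -> "AugmentSpec":
        """All ranges degenerate: augmentation becomes a voxel-exact no-op."""
        return cls(
            gaussian_noise_sigma=(0.0, 0.0),
            rotation_deg=(0.0, 0.0),
            flip_prob=0.0,
            transpose=False,
            shift_frac=(0.0, 0.0),
            shear_frac=(0.0, 0.0),
            resize_factor=(1.0, 1.0),
        )


@dataclass
class AugmentDraw:
    """One concrete sample of all transform parameters.

    ``matrix`` and ``shift_vox`` define the affine stage about the volume
    centre: an input point p (voxel coords, after transpose/flip) maps to
    ``matrix^-1 @ (p - c) + c + shift_vox`` in the output.
    """

    permutation: tuple[int, int, int]
    flips: tuple[bool, bool, bool]
    matrix: np.ndarray            # pull-back matrix used by the resampler
    shift_vox: np.ndarray
    noise_sigma: float
    noise_seed: int
    shape: tuple[int, int, int]

    def is_identity_geometry(self) -> bool:
        return (
            self.permutation == (0, 1, 2)
            and not any(self.flips)
            and np.allclose(self.matrix, np.eye(3), atol=1e-12)
            and np.allclose(self.shift_vox, 0.0, atol=1e-12)
        )

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map input voxel coordinates to output voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        pts = pts[:, list(self.permutation)]
        shape = np.asarray(self.shape, dtype=float)
        for ax, flip in enumerate(self.flips):
            if flip:
                pts[:, ax] = shape[ax] - 1 - pts[:, ax]
        c = (shape - 1) / 2.0
        inv = np.linalg.inv(self.matrix)
        out = (pts - c) @ inv.T + c + self.shift_vox
        return out


def sample_draw(
    spec: AugmentSpec, shape: tuple[int, int, int], rng: np.random.Generator
) -> AugmentDraw:
    """Sample one set of transform parameters for a volume of ``shape``."""
    if spec.transpose:
        perm = tuple(rng.permutation(3))
    else:
        perm = (0, 1, 2)
    flips = tuple(bool(rng.random() < spec.flip_prob) for _ in range(3))
    out_shape = tuple(shape[p] for p in perm)

    angles = rng.uniform(*spec.rotation_deg, size=3) * np.pi / 180.0
    shears = rng.uniform(*spec.shear_frac, size=3)
    scale = rng.uniform(*spec.resize_factor)
    shifts = rng.uniform(*spec.shift_frac, size=3) * np.asarray(out_shape)
    sigma = rng.uniform(*spec.gaussian_noise_sigma)
    noise_seed = int(rng.integers(0, 2**31 - 1))

    rot = np.eye(3)
    for axis, ang in enumerate(angles):
        c, s = np.cos(ang), np.sin(ang)
        i, j = [a for a in range(3) if a != axis]
        r = np.eye(3)
        r[i, i], r[i, j], r[j, i], r[j, j] = c, -s, s, c
        rot = r @ rot
    shear = np.eye(3)
    shear[0, 1], shear[1, 2], shear[2, 0] = shears
    forward = rot @ shear * scale
    # scipy's affine_transform pulls back: input = matrix @ output + offset,
    # so store the inverse of the forward map.
    matrix = np.linalg.inv(forward)
    return AugmentDraw(perm, flips, matrix, shifts, float(sigma), noise_seed,
                       out_shape)


def apply_draw(
    vol: Volume, labels: LabelMap, draw: AugmentDraw
) -> tuple[Volume, LabelMap]:
    """Apply one sampled draw to a volume/label pair."""
    if vol.data.shape != labels.data.shape:
        raise ValueError(
            f"volume lattice {vol.data.shape} != label lattice {labels.data.shape}"
        )
    data = np.transpose(vol.data, draw.permutation)
    lab = np.transpose(labels.data, draw.permutation)
    for ax, flip in enumerate(draw.flips):
        if flip:
            data = np.flip(data, axis=ax)
            lab = np.flip(lab, axis=ax)
    data = np.ascontiguousarray(data, dtype=np.float64)
    lab = np.ascontiguousarray(lab)

    if not draw.is_identity_geometry():
        c = (np.asarray(data.shape) - 1) / 2.0
        # output o draws from input matrix @ (o - c - shift) + c
        offset = draw.matrix @ (-c - draw.shift_vox) + c
        data = ndimage.affine_transform(
            data, draw.matrix, offset=offset, order=1, mode="constant", cval=0.0
        )
        lab = ndimage.affine_transform(
            lab, draw.matrix, offset=offset, order=0, mode="constant", cval=0
        )

    if draw.noise_sigma > 0:
        scale = float(np.percentile(data, 99))
        rng = np.random.default_rng(draw.noise_seed)
        data = data + rng.normal(0.0, draw.noise_sigma * max(scale, 1e-12),
                                 size=data.shape)

    spacing = tuple(vol.spacing[p] for p in draw.permutation)
    out_vol = Volume(data, spacing, vol.affine.copy(), vol.orientation_code)
    return out_vol, LabelMap(lab.astype(labels.data.dtype), dict(labels.class_codes))


def augment_pair(
    vol: Volume, labels: LabelMap, spec: AugmentSpec, draw_seed: int
) -> tuple[Volume, LabelMap]:
    """One random draw of all enabled transforms, deterministic in ``draw_seed``."""
    rng = np.random.default_rng(draw_seed)
    draw = sample_draw(spec, vol.data.shape, rng)
    return apply_draw(vol, labels, draw)


def epoch_size(n_originals: int, k_augment: int, include_originals: bool = True) -> int:
    """Images seen per epoch: the originals plus ``k_augment`` augments each.

    With the full protocol (3 augments per training image) a 144-image
    training set yields 576 images per epoch and a 48-image validation set
    with 1 augment each yields 96.
    """
    if n_originals < 1:
        raise ValueError("n_originals must be >= 1")
    if k_augment < 0:
        raise ValueError("k_augment must be >= 0")
    return n_originals * ((1 if include_originals else 0) + k_augment)


def make_epoch_stream(
    cohort: Sequence[tuple[Volume, LabelMap]],
    spec: AugmentSpec,
    k_augment: int,
    epoch_seed: int,
) -> Iterator[tuple[Volume, LabelMap]]:
    """Yield one epoch: each original unmodified, then ``k_augment`` fresh draws.

    Draw seeds derive from ``epoch_seed`` and the item index, so different
    epochs see different augmented data while remaining reproducible.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    seeds = np.random.SeedSequence(epoch_seed).generate_state(
        len(cohort) * max(k_augment, 1)
    )
    i = 0
    for vol, labels in cohort:
        yield vol, labels
        for _ in range(k_augment):
            yield augment_pair(vol, labels, spec, int(seeds[i] & 0x7FFFFFFF))
            i += 1
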