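"""Synthetic T1-like head phantoms with ground-truth facial-feature labels.

A phantom is a bright ellipsoidal head on a dark air background with four
attached structures: two spherical eyes on the anterior-superior surface, a
protruding nose on the anterior midline, and two lateral auricles.  The label
map follows the labelling protocol used for the detector's training data:
eye and nose labels are spheres around the feature centre, ear labels are the
full auricle protrusion (the part of the ear outside the head ellipsoid).

Axis convention (canonical RAS): axis 0 lateral (left -> right), axis 1
posterior -> anterior, axis 2 inferior -> superior.

The air background is half-normal noise (magnitude of a Gaussian), scaled so
its standard deviation equals ``air_noise_sigma``; head tissue carries mild
truncated-Gaussian texture around ``tissue_intensity``.  Phantoms are not MR
physics simulations — there is no bias field, partial voluming, or Rician
coil profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import Volume

#: Semantic classes shared across the package.
CLASS_CODES = {0: "background", 1: "eye", 2: "nose", 3: "ear"}

#: std(|N(0,1)|) = sqrt(1 - 2/pi); divides sigma so the air sample std
#: equals the requested air_noise_sigma.
_HALF_NORMAL_STD = float(np.sqrt(1.0 - 2.0 / np.pi))


class PhantomSpecError(ValueError):
    """Raised when a phantom's features would not fit inside its grid."""


@dataclass
class LabelMap:
    """Integer-coded feature labels on the same lattice as a Volume."""

    data: np.ndarray
    class_codes: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.class_codes is None:
            self.class_codes = dict(CLASS_CODES)
        if self.data.ndim != 3:
            raise ValueError("label map must be 3D")
        values = np.unique(self.data)
        if not np.isin(values, list(self.class_codes)).all():
            raise ValueError(f"label values {values} outside {sorted(self.class_codes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic head.

    Lengths are millimetres; the grid is ``grid_size`` voxels per axis at
    ``spacing`` mm per voxel, so the same head can be rendered at different
    resolutions.
    """

    grid_size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_radii: tuple[float, float, float] = (20.0, 22.0, 24.0)
    eye_radius: float = 5.0
    nose_extent: float = 6.0
    ear_extent: float = 6.0
    tissue_intensity: float = 100.0
    air_noise_sigma: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.air_noise_sigma < 0:
            raise PhantomSpecError("air_noise_sigma must be >= 0")
        if self.tissue_intensity <= 5 * self.air_noise_sigma:
            raise PhantomSpecError(
                "tissue_intensity must exceed 5 x air_noise_sigma so features "
                "are distinguishable from air noise"
            )
        half = [0.5 * n * s for n, s in zip(self.grid_size, self.spacing)]
        rx, ry, rz = self.head_radii
        needed = (
            rx + self.ear_extent + 1.0,      # lateral: head + auricle
            ry + self.nose_extent + 1.0,     # anterior: head + nose
            rz + 1.0,
        )
        for axis, (need, have) in enumerate(zip(needed, half)):
            if need > have:
                raise PhantomSpecError(
                    f"features extend {need:.1f} mm along axis {axis} but the "
                    f"grid half-extent is only {have:.1f} mm"
                )

    def small(self) -> "PhantomSpec":
        """The same head rendered on a 32-voxel grid at 2 mm spacing."""
        return replace(self, grid_size=(32, 32, 32), spacing=(2.0, 2.0, 2.0))


def _mm_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_size, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _feature_centers(spec: PhantomSpec) -> dict:
    """Feature centres in head-centred mm, derived from the head radii."""
    rx, ry, rz = spec.head_radii
    ex, ez = 0.5 * rx, (1.0 / 3.0) * rz           # eye lateral / superior offset
    inside = 1.0 - (ex / rx) ** 2 - (ez / rz) ** 2
    ey = ry * float(np.sqrt(max(inside, 0.0)))     # on the ellipsoid surface
    return {
        "eye_left": (-ex, ey, ez),
        "eye_right": (ex, ey, ez),
        "nose": (0.0, ry, 0.0),
        "ear_left": (-(rx + spec.ear_extent / 2.0 - 1.0), -2.0, 0.0),
        "ear_right": (rx + spec.ear_extent / 2.0 - 1.0, -2.0, 0.0),
    }


def make_head_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Render one phantom; bit-identical for a given spec (including seed)."""
    spec.validate()
    x, y, z = _mm_grid(spec)
    centers = _feature_centers(spec)
    rx, ry, rz = spec.head_radii

    head = _ellipsoid(x, y, z, (0.0, 0.0, 0.0), spec.head_radii)
    r_eye = spec.eye_radius
    eye_l = _ellipsoid(x, y, z, centers["eye_left"], (r_eye,) * 3)
    eye_r = _ellipsoid(x, y, z, centers["eye_right"], (r_eye,) * 3)
    # nose: ellipsoid straddling the anterior face; the protruding half forms
    # the visible nose
    nose_struct = _ellipsoid(
        x, y, z, centers["nose"], (0.75 * spec.nose_extent, spec.nose_extent,
                                   spec.nose_extent)
    )
    ear_axes = (spec.ear_extent / 2.0 + 1.5, 7.0, 9.0)
    ear_l = _ellipsoid(x, y, z, centers["ear_left"], ear_axes)
    ear_r = _ellipsoid(x, y, z, centers["ear_right"], ear_axes)

    tissue = head | eye_l | eye_r | nose_struct | ear_l | ear_r

    labels = np.zeros(spec.grid_size, dtype=np.int16)
    # ear label: auricle only — the protrusion outside the head ellipsoid
    labels[(ear_l | ear_r) & ~head] = 3
    # nose label: sphere about the nose centre, restricted to tissue
    nose_label = _ellipsoid(
        x, y, z, centers["nose"], (spec.nose_extent + 1.0,) * 3
    ) & tissue
    labels[nose_label] = 2
    labels[eye_l | eye_r] = 1

    rng = np.random.default_rng(spec.seed)
    sigma = spec.air_noise_sigma
    data = np.zeros(spec.grid_size, dtype=np.float64)
    if sigma > 0:
        air_noise = np.abs(rng.normal(0.0, sigma / _HALF_NORMAL_STD,
                                      size=spec.grid_size))
        texture = np.clip(rng.normal(0.0, sigma, size=spec.grid_size),
                          -3 * sigma, 3 * sigma)
        data[~tissue] = air_noise[~tissue]
        data[tissue] = spec.tissue_intensity + texture[tissue]
    else:
        data[tissue] = spec.tissue_intensity
    data = np.clip(data, 0.0, None)

    affine = np.diag(list(spec.spacing) + [1.0])
    affine[:3, 3] = [-(n - 1) / 2.0 * s for n, s in zip(spec.grid_size, spec.spacing)]
    vol = Volume(data, spec.spacing, affine)
    return vol, LabelMap(labels)


def make_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: float = 0.08,
    seed: int = 0,
) -> list[tuple[Volume, LabelMap]]:
    """``n`` phantoms with per-subject jitter of sizes and intensity.

    Each geometric parameter is scaled by an independent uniform factor in
    ``[1 - jitter, 1 + jitter]``.  ``jitter=0`` degenerates to ``n`` copies
    of the base phantom.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    if jitter == 0:
        pair = make_head_phantom(base_spec)
        return [pair] * n
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        f = rng.uniform(1 - jitter, 1 + jitter, size=7)
        spec = replace(
            base_spec,
            head_radii=tuple(r * fi for r, fi in zip(base_spec.head_radii, f[:3])),
            eye_radius=base_spec.eye_radius * f[3],
            nose_extent=base_spec.nose_extent * f[4],
            ear_extent=base_spec.ear_extent * f[5],
            tissue_intensity=base_spec.tissue_intensity * f[6],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(make_head_phantom(spec))
    return cohort


def train_val_test_split(
    items: Sequence, ratios: tuple[int, int, int] = (3, 1, 1)
) -> tuple[list, list, list]:
    """Deterministic ordered split in the given ratio (default 3:1:1)."""
    total = sum(ratios)
    n = len(items)
    n_train = round(n * ratios[0] / total)
    n_val = round(n * ratios[1] / total)
    return (
        list(items[:n_train]),
        list(items[n_train:n_train + n_val]),
        list(items[n_train + n_val:]),
    )
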