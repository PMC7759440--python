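"""Feature-specific anonymization operators for detected facial regions.

Each facial feature is distorted the way that best hides it while
preserving nearby brain tissue:

* **nose** — the axis-aligned bounding box of the detected region is doubled
  in side length about its centre along every axis and every voxel inside is
  set to 0, so the nose shape cannot be inferred;
* **eyes** — a periocular box is built around each eye, the face surface is
  traced inside it, and a shell of +-2 voxels about the surface is flattened
  to one constant intensity (the median surface intensity), blurring the
  periocular skin in any surface rendering;
* **ears** — every voxel of the detected auricle is replaced by an
  independent uniform draw from the air-noise intensity range of the input
  image, so the auricle disappears into the background noise.

All masks are resolved on the *input* volume, and in the composed
:func:`deface` the operators claim voxels with precedence nose > eyes >
ears, so their modification zones are disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Volume

#: Margin (voxels) of the outer faces used to sample air.
_AIR_MARGIN = 8

#: Air sample = margin voxels below this fraction of the robust maximum.
_AIR_TISSUE_FRACTION = 0.25

#: Percentile of the air sample reported as the top of the noise range.
_AIR_HI_PERCENTILE = 98.0

#: Face-surface threshold = this multiple of the air-range top.
_SURFACE_THRESHOLD_FACTOR = 3.0

#: Chebyshev radius of the flattened shell about the face surface.
_SHELL_RADIUS = 2

#: Periocular box expansion factor (lateral and vertical axes).
_PERIOCULAR_EXPAND = 2.0


@dataclass
class DetectionRegions:
    """Instance masks for the five facial regions on one volume's lattice."""

    eye_left: np.ndarray
    eye_right: np.ndarray
    nose: np.ndarray
    ear_left: np.ndarray
    ear_right: np.ndarray
    present: dict[str, bool] = field(default_factory=dict)

    FEATURES = ("eye_left", "eye_right", "nose", "ear_left", "ear_right")

    def __post_init__(self) -> None:
        shapes = {getattr(self, f).shape for f in self.FEATURES}
        if len(shapes) != 1:
            raise ValueError("region masks must share one lattice")
        if not self.present:
            self.present = {f: bool(getattr(self, f).any()) for f in self.FEATURES}
        stack = np.stack([getattr(self, f) for f in self.FEATURES]).astype(bool)
        if (stack.sum(axis=0) > 1).any():
            raise ValueError("region masks must be pairwise disjoint")

    def mask(self, feature: str) -> np.ndarray:
        return np.asarray(getattr(self, feature), dtype=bool)

    def n_present(self) -> int:
        return sum(self.present.values())


@dataclass
class AirNoiseRange:
    """Intensity interval spanned by background (air) voxels."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo must be <= hi")
        if self.lo < 0:
            raise ValueError("lo must be >= 0 for magnitude images")


def estimate_air_noise(vol: Volume) -> AirNoiseRange:
    """Estimate the air-noise intensity range of a magnitude MR volume.

    Air is sampled from the 8-voxel margin of the six outer faces, keeping
    voxels below 25% of the volume's 99th-percentile intensity (a robust,
    scale-invariant cut that rejects tissue touching the margin).  The range
    is [0, 98th percentile of that sample].  A uniformly bright volume with
    no air falls back to [0, 1% of max] with a warning.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    margin = np.ones(data.shape, dtype=bool)
    m = _AIR_MARGIN
    if all(s > 2 * m for s in data.shape):
        margin[m:-m, m:-m, m:-m] = False
    robust_max = float(np.percentile(data, 99))
    air = data[margin & (data < _AIR_TISSUE_FRACTION * robust_max)]
    if air.size == 0:
        warnings.warn("no air voxels found; falling back to [0, 1% of max]")
        return AirNoiseRange(0.0, 0.01 * float(data.max()))
    return AirNoiseRange(0.0, float(np.percentile(air, _AIR_HI_PERCENTILE)))


# ---------------------------------------------------------------------------
# Boxes
# ---------------------------------------------------------------------------

def bounding_box(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Half-open [lo, hi) bounding box of a non-empty mask, per axis."""
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise ValueError("mask is empty")
    return tuple((int(a.min()), int(a.max()) + 1) for a in idx)


def doubled_box(
    box: tuple[tuple[int, int], ...], shape: tuple[int, int, int]
) -> tuple[tuple[int, int], ...]:
    """Box with side length doubled about its centre, clipped to the volume."""
    out = []
    for (lo, hi), n in zip(box, shape):
        c = (lo + hi) / 2.0
        half = (hi - lo)  # doubled half-extent = old full extent
        new_lo = int(np.floor(c - half))
        new_hi = int(np.ceil(c + half))
        out.append((max(new_lo, 0), min(new_hi, n)))
    return tuple(out)


def _box_slices(box) -> tuple[slice, ...]:
    return tuple(slice(lo, hi) for lo, hi in box)


# ---------------------------------------------------------------------------
# Nose
# ---------------------------------------------------------------------------

def deface_nose(vol: Volume, nose: np.ndarray) -> Volume:
    """Zero the doubled bounding box of the nose region."""
    out = vol.data.copy()
    if not np.asarray(nose, dtype=bool).any():
        warnings.warn("nose mask is empty; volume unchanged")
        return vol.with_data(out)
    box = doubled_box(bounding_box(nose), vol.data.shape)
    out[_box_slices(box)] = 0.0
    return vol.with_data(out)


def nose_zone(vol: Volume, nose: np.ndarray) -> np.ndarray:
    """Boolean mask of the voxels :func:`deface_nose` would zero."""
    zone = np.zeros(vol.data.shape, dtype=bool)
    if np.asarray(nose, dtype=bool).any():
        zone[_box_slices(doubled_box(bounding_box(nose), vol.data.shape))] = True
    return zone


# ---------------------------------------------------------------------------
# Eyes
# ---------------------------------------------------------------------------

def periocular_box(
    eye_mask: np.ndarray, shape: tuple[int, int, int]
) -> tuple[tuple[int, int], ...]:
    """Box covering the skin around one eye.

    The eye's bounding box is expanded by a factor of 2 along the lateral
    (axis 0) and vertical (axis 2) axes and extended to the anterior volume
    face along axis 1, so the skin in front of the eyeball is always inside.
    """
    (x0, x1), (y0, y1), (z0, z1) = bounding_box(eye_mask)
    out = []
    for lo, hi, n in (((x0), (x1), shape[0]), ((z0), (z1), shape[2])):
        c = (lo + hi) / 2.0
        half = (hi - lo) / 2.0 * _PERIOCULAR_EXPAND
        out.append((max(int(np.floor(c - half)), 0), min(int(np.ceil(c + half)), n)))
    (bx, bz) = out
    return (bx, (y0, shape[1]), bz)


def _find_surface(data: np.ndarray, box, threshold: float) -> np.ndarray:
    """Face-surface voxels inside ``box``: per (x, z) column, the first voxel
    exceeding ``threshold`` when scanning from the anterior face inward.

    Two guards make repeated defacing a fixed point rather than a creeping
    erosion.  First, an exactly-constant supra-threshold run of 3-5 voxels
    at the crossing is recentred to the run centre: a previously flattened
    shell is exactly constant over its 5-voxel depth, so re-defacing finds
    the original surface, while natural tissue has texture and never forms
    such runs.  Second, a column is skipped when the crossing sits behind an
    exactly-zero cavity (>= 3 zero voxels with nonzero air above them) — the
    signature of an already-removed nose box, never of real anatomy, where
    air carries noise.
    """
    (x0, x1), (y0, y1), (z0, z1) = box
    surface = np.zeros(data.shape, dtype=bool)
    above = data[x0:x1, y0:y1, z0:z1] > threshold
    any_above = above.any(axis=1)
    # first supra-threshold index scanning anterior (high y) -> posterior
    first_rev = above[:, ::-1, :].argmax(axis=1)
    ys = (y1 - y0) - 1 - first_rev + y0
    ny = data.shape[1]
    xs, zs = np.nonzero(any_above)
    for xi, zi in zip(xs, zs):
        yi = int(ys[xi, zi])
        # guards read the full-volume column so the box edge cannot truncate
        # the constant-run or zero-cavity patterns
        column = data[x0 + xi, :, z0 + zi]
        zeros = 0
        while yi + 1 + zeros < ny and column[yi + 1 + zeros] == 0.0:
            zeros += 1
        if zeros >= 3 and (column[yi + 1 + zeros:] > 0).any():
            continue  # crossing is the back wall of a removed nose box
        v = column[yi]
        run = 1
        while yi - run >= 0 and column[yi - run] == v and run <= 5:
            run += 1
        if 3 <= run <= 5:
            yi -= (run - 1) // 2
        surface[x0 + xi, yi, z0 + zi] = True
    return surface


def eye_shell(
    vol: Volume, eye_left: np.ndarray, eye_right: np.ndarray,
    air: AirNoiseRange | None = None,
    exclude_zone: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """The voxel set :func:`deface_eyes` flattens, and the fill value.

    Per periocular-box column, the shell is the +-2-voxel segment along the
    anterior axis about the detected surface voxel; the fill value is the
    median intensity over surface voxels of both boxes.  If an
    ``exclude_zone`` is given (the nose box in the composed pipeline),
    columns whose segment would intersect it are left untouched entirely,
    keeping the two operators' zones disjoint and stable under repetition.
    """
    if air is None:
        air = estimate_air_noise(vol)
    threshold = _SURFACE_THRESHOLD_FACTOR * air.hi
    data = np.asarray(vol.data, dtype=np.float64)
    shell = np.zeros(data.shape, dtype=bool)
    surface_values: list[np.ndarray] = []
    ny = data.shape[1]
    for mask in (eye_left, eye_right):
        if not np.asarray(mask, dtype=bool).any():
            continue
        box = periocular_box(mask, data.shape)
        surface = _find_surface(data, box, threshold)
        if not surface.any():
            continue
        kept = []
        for xi, yi, zi in np.argwhere(surface):
            lo = max(yi - _SHELL_RADIUS, 0)
            hi = min(yi + _SHELL_RADIUS + 1, ny)
            if exclude_zone is not None and exclude_zone[xi, lo:hi, zi].any():
                continue
            shell[xi, lo:hi, zi] = True
            kept.append((xi, yi, zi))
        if kept:
            idx = tuple(np.array(kept).T)
            surface_values.append(data[idx])
    if not surface_values:
        return shell, 0.0
    fill = float(np.median(np.concatenate(surface_values)))
    return shell, fill


def deface_eyes(
    vol: Volume, eye_left: np.ndarray, eye_right: np.ndarray,
    air: AirNoiseRange | None = None,
) -> Volume:
    """Flatten the periocular face surface to one constant intensity."""
    if not (np.asarray(eye_left, dtype=bool).any()
            or np.asarray(eye_right, dtype=bool).any()):
        warnings.warn("both eye masks are empty; volume unchanged")
        return vol.with_data(vol.data.copy())
    shell, fill = eye_shell(vol, eye_left, eye_right, air)
    out = vol.data.copy()
    out[shell] = fill
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# Ears
# ---------------------------------------------------------------------------

def deface_ears(
    vol: Volume, ear_left: np.ndarray, ear_right: np.ndarray,
    air: AirNoiseRange | None = None, seed: int = 0,
) -> Volume:
    """Replace auricle voxels with uniform draws from the air-noise range."""
    if air is None:
        air = estimate_air_noise(vol)
    mask = np.asarray(ear_left, dtype=bool) | np.asarray(ear_right, dtype=bool)
    out = vol.data.copy()
    n = int(mask.sum())
    if n:
        rng = np.random.default_rng(seed)
        if air.hi > air.lo:
            out[mask] = rng.uniform(air.lo, air.hi, size=n)
        else:
            out[mask] = air.lo
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def deface(
    vol: Volume,
    regions: DetectionRegions,
    enable: dict[str, bool] | None = None,
    seed: int = 0,
) -> tuple[Volume, dict]:
    """Apply the enabled operators (nose -> eyes -> ears) to one volume.

    All masks, the air-noise range, and the face surface are resolved on the
    input volume, and overlapping claims are resolved with precedence
    nose > eyes > ears, so the three modification zones are disjoint and
    their union is exactly the set of changed-or-claimed voxels.  Returns the
    anonymized volume and a report of per-feature modified voxel counts.
    """
    if regions.eye_left.shape != vol.data.shape:
        raise ValueError("regions are not on the volume's lattice")
    toggles = {"nose": True, "eyes": True, "ears": True}
    if enable:
        toggles.update(enable)
    report: dict = {"features": {}, "warnings": [], "seed": seed}
    out = vol.data.copy()
    air = estimate_air_noise(vol)
    claimed = np.zeros(vol.data.shape, dtype=bool)

    if toggles["nose"]:
        if regions.present.get("nose", False):
            zone = nose_zone(vol, regions.mask("nose"))
            out[zone] = 0.0
            claimed |= zone
            report["features"]["nose"] = {"modified_voxels": int(zone.sum())}
        else:
            report["warnings"].append("nose absent; skipped")
            report["features"]["nose"] = {"modified_voxels": 0}

    if toggles["eyes"]:
        if regions.present.get("eye_left", False) or regions.present.get(
                "eye_right", False):
            shell, fill = eye_shell(vol, regions.eye_left, regions.eye_right, air,
                                    exclude_zone=claimed)
            shell &= ~claimed
            out[shell] = fill
            claimed |= shell
            report["features"]["eyes"] = {
                "modified_voxels": int(shell.sum()), "fill_value": fill,
            }
        else:
            report["warnings"].append("both eyes absent; skipped")
            report["features"]["eyes"] = {"modified_voxels": 0}

    if toggles["ears"]:
        ear_mask = regions.mask("ear_left") | regions.mask("ear_right")
        ear_mask &= ~claimed
        n = int(ear_mask.sum())
        if n:
            rng = np.random.default_rng(seed)
            if air.hi > air.lo:
                out[ear_mask] = rng.uniform(air.lo, air.hi, size=n)
            else:
                out[ear_mask] = air.lo
            claimed |= ear_mask
        elif not (regions.present.get("ear_left", False)
                  or regions.present.get("ear_right", False)):
            report["warnings"].append("both ears absent; skipped")
        report["features"]["ears"] = {"modified_voxels": n}

    report["total_modified_voxels"] = int(claimed.sum())
    report["air_noise_range"] = [air.lo, air.hi]
    return vol.with_data(out), report
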