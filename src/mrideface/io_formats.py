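"""Reading and writing cranial MR volumes, plus DICOM header de-identification.

NIfTI-1 files are handled through :mod:`nibabel` and DICOM series through
:mod:`pydicom`.  On load every volume is reoriented to the closest-to-RAS
axis order so that downstream code can rely on a fixed anatomical frame:

* axis 0 — left → right (lateral),
* axis 1 — posterior → anterior,
* axis 2 — inferior → superior.

The original affine is preserved on the :class:`Volume` so a defaced copy can
be written back on the grid it came from.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset
from pydicom.tag import Tag


class FormatError(ValueError):
    """Raised when an on-disk image cannot be parsed."""


class DimensionalityError(FormatError):
    """Raised when a volume does not have exactly three spatial dimensions."""


# ---------------------------------------------------------------------------
# Volume container
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and grid-to-world affine.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary MR units), canonical axis order.
    spacing:
        Millimetres per voxel along each axis; all components positive.
    affine:
        4x4 invertible grid-to-world map (voxel indices -> mm).
    orientation_code:
        Axis-label triple such as ``('R', 'A', 'S')``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    orientation_code: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"volume data must be 3D, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        """A copy of this volume carrying ``data`` on the same lattice."""
        if data.shape != self.data.shape:
            raise ValueError(
                f"replacement data shape {data.shape} != lattice {self.data.shape}"
            )
        return Volume(data, self.spacing, self.affine.copy(), self.orientation_code)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def read_nifti(path: str | Path, first_frame: bool = False) -> Volume:
    """Load a NIfTI-1 file as a canonically oriented :class:`Volume`.

    Scaling slope/intercept from the header are applied, so intensities match
    what any NIfTI viewer displays.  4D inputs raise unless ``first_frame``
    is set, in which case volume 0 is extracted.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    try:
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.get_fdata(dtype=np.float64))
    except Exception as exc:
        raise FormatError(f"cannot decode NIfTI file {path}: {exc}") from exc
    if data.ndim == 4:
        if not first_frame:
            raise DimensionalityError(
                f"{path} is 4D; pass first_frame=True to extract volume 0"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path} has {data.ndim} dimensions, expected 3")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    code = nib.aff2axcodes(img.affine)
    return Volume(data, spacing, np.asarray(img.affine), code)


def write_nifti(vol: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` to a ``.nii`` / ``.nii.gz`` file."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _slice_normal(ds: Dataset) -> np.ndarray:
    iop = np.asarray([float(v) for v in ds.ImageOrientationPatient], dtype=float)
    return np.cross(iop[:3], iop[3:])


def read_dicom_series(directory: str | Path) -> Volume:
    """Assemble one single-frame DICOM series from ``directory`` into a Volume.

    Slices are sorted by the projection of ImagePositionPatient onto the slice
    normal, so the result is independent of on-disk file order.  Inter-slice
    spacing is measured from consecutive positions.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets: list[Dataset] = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue  # non-DICOM clutter is ignored
    if not datasets:
        raise FormatError(f"no readable DICOM files in {directory}")

    uids = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(uids) > 1:
        raise FormatError(
            f"directory {directory} mixes {len(uids)} series: {', '.join(uids)}"
        )
    for ds in datasets:
        if "ImagePositionPatient" not in ds:
            raise FormatError("DICOM slice is missing ImagePositionPatient")

    normal = _slice_normal(datasets[0])
    positions = [float(np.dot(normal, np.asarray(ds.ImagePositionPatient, dtype=float)))
                 for ds in datasets]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    rows, cols = int(datasets[0].Rows), int(datasets[0].Columns)
    stack = np.stack([ds.pixel_array.astype(np.float64) for ds in datasets], axis=-1)
    if stack.shape[:2] != (rows, cols):
        raise FormatError("inconsistent slice dimensions within the series")

    pixel_spacing = [float(v) for v in datasets[0].PixelSpacing]
    if len(datasets) > 1:
        gaps = np.diff(positions)
        slice_spacing = float(np.mean(gaps))
        if slice_spacing <= 0 or np.any(gaps <= 0):
            raise FormatError("duplicate or non-monotonic slice positions")
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    # LPS -> voxel affine from orientation cosines, then hand to nibabel's
    # canonical reorientation by converting to RAS.
    iop = np.asarray([float(v) for v in datasets[0].ImageOrientationPatient])
    ipp0 = np.asarray([float(v) for v in datasets[0].ImagePositionPatient])
    affine_lps = np.eye(4)
    # pixel_array axis 0 is the row index, which advances along iop[3:6]
    affine_lps[:3, 0] = iop[3:] * pixel_spacing[0]
    affine_lps[:3, 1] = iop[:3] * pixel_spacing[1]
    affine_lps[:3, 2] = normal * slice_spacing
    affine_lps[:3, 3] = ipp0
    affine_ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine_lps

    img = nib.Nifti1Image(stack, affine_ras)
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    spacing = tuple(float(abs(z)) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, np.asarray(img.affine), nib.aff2axcodes(img.affine))


# ---------------------------------------------------------------------------
# De-identification
# ---------------------------------------------------------------------------

#: Actions understood by :func:`deidentify_dicom`.
ACTIONS = ("remove", "blank", "replace")

#: Default profile: 20 HIPAA-safe-harbor-aligned attributes.  Users may load
#: their own list with :func:`load_deid_profile`.
DEFAULT_DEID_ATTRIBUTES: tuple[tuple[int, int, str], ...] = (
    (0x0010, 0x0010, "remove"),   # PatientName
    (0x0010, 0x0020, "remove"),   # PatientID
    (0x0010, 0x0030, "remove"),   # PatientBirthDate
    (0x0010, 0x1000, "remove"),   # OtherPatientIDs
    (0x0010, 0x1001, "remove"),   # OtherPatientNames
    (0x0010, 0x1005, "remove"),   # PatientBirthName
    (0x0010, 0x1040, "remove"),   # PatientAddress
    (0x0010, 0x2154, "remove"),   # PatientTelephoneNumbers
    (0x0010, 0x2160, "remove"),   # EthnicGroup
    (0x0010, 0x4000, "remove"),   # PatientComments
    (0x0008, 0x0080, "blank"),    # InstitutionName
    (0x0008, 0x0081, "blank"),    # InstitutionAddress
    (0x0008, 0x0090, "blank"),    # ReferringPhysicianName
    (0x0008, 0x1050, "blank"),    # PerformingPhysicianName
    (0x0008, 0x1070, "blank"),    # OperatorsName
    (0x0008, 0x0050, "blank"),    # AccessionNumber
    (0x0008, 0x0020, "blank"),    # StudyDate
    (0x0008, 0x0021, "blank"),    # SeriesDate
    (0x0008, 0x0030, "blank"),    # StudyTime
    (0x0018, 0x1000, "remove"),   # DeviceSerialNumber
)

#: Replacement UIDs are regenerated under this root; values already under it
#: are left untouched so repeated de-identification is a no-op.
_UID_ROOT = "1.2.826.0.1.3680043.8.498."


@dataclass
class DeidProfile:
    """Ordered list of DICOM attributes to scrub and the action for each."""

    attributes: list[tuple[int, int, str]] = field(
        default_factory=lambda: list(DEFAULT_DEID_ATTRIBUTES)
    )

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for group, elem, action in self.attributes:
            if action not in ACTIONS:
                raise ValueError(f"unknown action {action!r}")
            if (group, elem) in seen:
                raise ValueError(
                    f"duplicate attribute ({group:04x},{elem:04x}) in profile"
                )
            seen.add((group, elem))

    def __len__(self) -> int:
        return len(self.attributes)


def default_deid_profile() -> DeidProfile:
    """The 20-attribute HIPAA-safe-harbor-aligned default profile."""
    return DeidProfile()


def load_deid_profile(path: str | Path) -> DeidProfile:
    """Read a profile from a plain-text file: one ``group,element,action`` per line."""
    attrs: list[tuple[int, int, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise ValueError(f"bad profile line: {raw!r}")
        attrs.append((int(parts[0], 16), int(parts[1], 16), parts[2]))
    return DeidProfile(attrs)


def save_deid_profile(profile: DeidProfile, path: str | Path) -> None:
    lines = [f"{g:04x},{e:04x},{a}" for g, e, a in profile.attributes]
    Path(path).write_text("\n".join(lines) + "\n")


def _replacement_uid(original: str) -> str:
    digest = hashlib.md5(original.encode()).hexdigest()[:16]
    return _UID_ROOT + str(int(digest, 16))


def deidentify_dicom(
    dataset: Dataset, profile: DeidProfile | None = None
) -> tuple[Dataset, list[dict]]:
    """Scrub header attributes from ``dataset`` per ``profile``.

    Returns a modified copy and an audit trail: one record per profile
    attribute with its tag, action, and status (``removed`` / ``blanked`` /
    ``replaced`` / ``absent``).  Pixel data is never touched, and applying
    the function twice equals applying it once.
    """
    if profile is None:
        profile = default_deid_profile()
    out = copy.deepcopy(dataset)
    audit: list[dict] = []
    for group, elem, action in profile.attributes:
        tag = Tag(group, elem)
        record = {"tag": f"({group:04x},{elem:04x})", "action": action}
        if tag not in out:
            record["status"] = "absent"
            audit.append(record)
            continue
        record["name"] = out[tag].name
        if action == "remove":
            del out[tag]
            record["status"] = "removed"
        elif action == "blank":
            out[tag].value = ""
            record["status"] = "blanked"
        else:  # replace: deterministic UID regeneration preserving linkage
            value = str(out[tag].value)
            if value.startswith(_UID_ROOT):
                record["status"] = "already-replaced"
            else:
                out[tag].value = _replacement_uid(value)
                record["status"] = "replaced"
        audit.append(record)
    return out, audit


def acted_on(audit: Iterable[dict]) -> list[dict]:
    """The subset of audit records where the dataset was actually modified."""
    return [r for r in audit if r["status"] in ("removed", "blanked", "replaced")]
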