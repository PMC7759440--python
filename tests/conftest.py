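"""Shared fixtures: phantoms, synthetic DICOM series, and cached training."""

from __future__ import annotations

import functools
import os

import numpy as np
import pydicom
import pytest
from pydicom.datadict import dictionary_VR
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.tag import Tag
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from mrideface.augmentation import AugmentSpec
from mrideface.detector import (
    DetectorConfig,
    TrainConfig,
    build_detector,
    train_detector,
)
from mrideface.io_formats import DEFAULT_DEID_ATTRIBUTES
from mrideface.phantom import PhantomSpec, make_cohort, make_head_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return make_head_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec().small()


# ---------------------------------------------------------------------------
# Synthetic DICOM builders
# ---------------------------------------------------------------------------

def make_dicom_slice(
    index: int, series_uid: str, study_uid: str, gap: float = 1.2,
    rows: int = 16, cols: int = 16, seed: int = 0,
) -> FileDataset:
    ds = FileDataset(None, {}, file_meta=FileMetaDataset(), preamble=b"\0" * 128)
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = pydicom.uid.MRImageStorage
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = study_uid
    ds.Modality = "MR"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [1.0, 1.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0, 0, index * gap]
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    rng = np.random.default_rng(seed * 1000 + index)
    ds.PixelData = rng.integers(0, 1000, (rows, cols), dtype=np.uint16).tobytes()
    return ds


def write_series(directory, n: int = 8, gap: float = 1.2, seed: int = 0,
                 name_order=None) -> None:
    series_uid, study_uid = generate_uid(), generate_uid()
    names = name_order or [f"slice_{i:03d}.dcm" for i in range(n)]
    for i in range(n):
        ds = make_dicom_slice(i, series_uid, study_uid, gap=gap, seed=seed)
        ds.save_as(os.path.join(directory, names[i]), enforce_file_format=True)


_SAMPLE_VALUES = {
    "PN": "Doe^Jane",
    "LO": "some-text",
    "SH": "ACC123",
    "DA": "19700102",
    "TM": "101530",
    "ST": "1 Example Street",
    "CS": "GROUP",
}


def populated_deid_dataset() -> Dataset:
    """A header carrying a plausible value for every default-profile tag."""
    ds = Dataset()
    for group, elem, _action in DEFAULT_DEID_ATTRIBUTES:
        tag = Tag(group, elem)
        vr = dictionary_VR(tag)
        ds.add_new(tag, vr, _SAMPLE_VALUES.get(vr, "value"))
    ds.add_new(Tag(0x7FE0, 0x0010), "OW", b"\x01\x02\x03\x04")
    return ds


# ---------------------------------------------------------------------------
# Cached desk-scale training (shared by recovery + end-to-end tests)
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=3)
def trained_small_detector(seed: int):
    """Train the depth-3 detector on 12 jittered phantoms at 32 voxels.

    Cached so the end-to-end pipeline test can reuse the recovery test's
    first model instead of training twice.
    """
    spec = PhantomSpec().small()
    train = make_cohort(12, spec, jitter=0.08, seed=100 + seed)
    val = make_cohort(4, spec, jitter=0.08, seed=200 + seed)
    model = build_detector(DetectorConfig.small(seed=seed))
    tconf = TrainConfig(max_epochs=15, seed=seed)
    model, history = train_detector(model, train, val, tconf, AugmentSpec(seed=seed))
    return model, history
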