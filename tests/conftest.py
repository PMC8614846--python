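"""Shared fixtures: phantoms, margins, and small DICOM files built at test time."""
import numpy as np
import pytest

from kneejsw.contour import build_frame, extract_margins
from kneejsw.imaging import normalize_intensity
from kneejsw.phantom import PhantomSpec, constant_gap, make_phantom, parabolic_gap

MM = 0.2  # pixel spacing used by the default phantoms, mm


@pytest.fixture(scope="session")
def flat_phantom():
    """Constant 4.0 mm gap with flat margins."""
    spec = PhantomSpec(tibia_curve_params=(150.0,), gap_profile=constant_gap(4.0),
                       mm_per_pixel=MM, seed=1)
    return make_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def parabolic_phantom():
    """Parabolic gap g(x) = 2 + 8 (x - 0.8)^2 mm: medial minimum 2.0 at x=0.8."""
    spec = PhantomSpec(gap_profile=parabolic_gap(2.0, 8.0, 0.8),
                       mm_per_pixel=MM, seed=2)
    return make_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def parabolic_margins(parabolic_phantom):
    _, mask, truth, spec = parabolic_phantom
    femur, tibia = extract_margins(mask)
    frame = build_frame(tibia, "right", MM, MM)
    return femur, tibia, frame, truth


def small_phantom_pairs(n: int = 5, side: int = 128):
    """Normalized radiograph/mask pairs for training runs."""
    pairs = []
    for i in range(n):
        spec = PhantomSpec(
            image_height=side, image_width=side,
            plateau_span=(side // 8, side - side // 8),
            tibia_curve_params=(0.1 * side, -0.1 * side, 0.72 * side),
            gap_profile=parabolic_gap(1.6 + 0.3 * i, 2.0, 0.78),
            mm_per_pixel=MM, seed=i)
        radiograph, mask, _ = make_phantom(spec)
        pairs.append((normalize_intensity(radiograph), mask))
    return pairs


@pytest.fixture()
def tiny_train_pairs():
    return small_phantom_pairs(n=2, side=32)


def write_test_dicom(path, rows=32, cols=32, spacing=(0.2, 0.2)):
    """Minimal valid Part-10 secondary-capture DICOM with pixel spacing."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Rows, ds.Columns = rows, cols
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    if spacing is not None:
        ds.PixelSpacing = list(spacing)
    ds.PixelData = np.arange(rows * cols, dtype=np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path
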