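"""Reading and writing CT volumes and masks with correct physical spacing.

Supported formats: NIfTI-1 (``.nii`` / ``.nii.gz``) through nibabel and DICOM
series directories through pydicom.  In memory everything is ``(z, y, x)``;
NIfTI files store ``(x, y, z)`` so axes are transposed on the way in and out.
DICOM slices are sorted by physical position along the slice normal, and
rescale slope/intercept are applied on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import BinaryMask, CTVolume, voxel_volume_mm3  # noqa: F401  (re-export)

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "write_dicom_series",
    "voxel_volume_mm3",
    "MissingSpacingError",
]

# Secondary Capture Image Storage: phantom exports are derived, not acquired.
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"


class MissingSpacingError(ValueError):
    """Raised when a file lacks the metadata needed to recover voxel spacing."""


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_to_zyx(img) -> tuple[np.ndarray, tuple[float, float, float]]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MissingSpacingError(
            f"NIfTI header pixdim carries no positive voxel spacing: {zooms}"
        )
    # nibabel axes are (x, y, z); flip to (z, y, x)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.transpose(data, (2, 1, 0)), spacing


def _zyx_to_nifti(data: np.ndarray, spacing_mm) -> nib.Nifti1Image:
    xyz = np.transpose(data, (2, 1, 0))
    affine = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    img = nib.Nifti1Image(xyz, affine)
    img.header.set_zooms((spacing_mm[2], spacing_mm[1], spacing_mm[0]))
    return img


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _load_dicom_dir(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".txt")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM stray file
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {path}")

    def z_of(ds) -> float:
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        inum = getattr(ds, "InstanceNumber", None)
        if inum is None:
            raise MissingSpacingError(
                "DICOM slice lacks both ImagePositionPatient and InstanceNumber; "
                "cannot order slices"
            )
        return float(inum)

    datasets.sort(key=z_of)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise MissingSpacingError("DICOM series lacks the PixelSpacing tag")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)

    if len(datasets) > 1 and hasattr(first, "ImagePositionPatient"):
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
        gaps = np.diff(zs)
        slice_sp = float(np.median(gaps))
        if slice_sp <= 0:
            raise MissingSpacingError("non-increasing slice positions in DICOM series")
        if np.any(np.abs(gaps - slice_sp) > 0.01 * slice_sp):
            warnings.warn(
                "inconsistent slice spacing in DICOM series; using the median gap",
                stacklevel=3,
            )
    else:
        slice_sp = getattr(first, "SpacingBetweenSlices", None) or getattr(
            first, "SliceThickness", None
        )
        if slice_sp is None:
            raise MissingSpacingError(
                "DICOM series lacks SpacingBetweenSlices/SliceThickness and has a "
                "single slice position"
            )
        slice_sp = float(slice_sp)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    data = np.stack(slices, axis=0)
    origin = (0.0, 0.0, 0.0)
    if hasattr(first, "ImagePositionPatient"):
        p = first.ImagePositionPatient
        origin = (float(p[2]), float(p[1]), float(p[0]))
    return CTVolume(
        data=data,
        spacing_mm=(slice_sp, row_sp, col_sp),
        origin=origin,
        source_id=str(path),
    )


def write_dicom_series(volume: CTVolume, out_dir) -> list[Path]:
    """Export a volume as one explicit-VR little-endian DICOM file per slice.

    PixelSpacing, SliceThickness/SpacingBetweenSlices and per-slice
    ImagePositionPatient are populated so the series round-trips through
    :func:`load_volume`.  Intensities are stored as int16 HU with identity
    rescale.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[volume.source_id or "ltq-phantom"])
    study_uid = generate_uid(entropy_srcs=[(volume.source_id or "ltq-phantom") + "/study"])
    sz, sy, sx = volume.spacing_mm
    paths = []
    data = np.rint(np.clip(volume.data, -32768, 32767)).astype(np.int16)
    for i in range(volume.shape[0]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = _SC_SOP_CLASS
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[f"{series_uid}/{i}"]
        )
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = _SC_SOP_CLASS
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = volume.source_id or "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [
            float(volume.origin[2]),
            float(volume.origin[1]),
            float(volume.origin[0] + i * sz),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sy, sx]
        ds.SliceThickness = sz
        ds.SpacingBetweenSlices = sz
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.Rows, ds.Columns = data.shape[1], data.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = data[i].tobytes()
        p = out / f"slice_{i:04d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def load_volume(path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom_dir"``; when omitted it is inferred
    from the path (directory -> DICOM, file -> NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    if format == "nifti":
        data, spacing = _nifti_to_zyx(nib.load(str(path)))
        return CTVolume(data=data.astype(np.float64), spacing_mm=spacing,
                        source_id=str(path))
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom_dir'")


def save_volume(volume: CTVolume, path) -> None:
    """Write a volume as NIfTI with spacing in the header."""
    img = _zyx_to_nifti(volume.data.astype(np.float32), volume.spacing_mm)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as a {0,1}-valued NIfTI with the companion spacing."""
    img = _zyx_to_nifti(mask.data.astype(np.uint8), mask.spacing_mm)
    nib.save(img, str(path))


def load_mask(path, role: str = "liver") -> BinaryMask:
    """Load a {0,1} NIfTI mask."""
    data, spacing = _nifti_to_zyx(nib.load(str(path)))
    return BinaryMask(data=data > 0.5, spacing_mm=spacing, role=role)
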