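"""Core in-memory containers for CT volumes and binary masks.

The canonical axis order everywhere in this package is ``(z, y, x)`` with
0-based indexing: axis 0 walks through axial slices, axes 1 and 2 are the
in-plane rows and columns.  Physical voxel spacing is carried alongside the
grid as ``(slice_spacing, row_spacing, col_spacing)`` in millimetres, so a
voxel occupies ``prod(spacing_mm)`` mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask",
    "voxel_volume_mm3",
    "MaskRole",
]

#: Recognised roles a mask can play in the pipeline.
MaskRole = ("liver", "trauma", "ground_truth_liver", "ground_truth_trauma")


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3:
        raise ValueError(f"spacing_mm must have 3 components, got {spacing_mm!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacing components must be > 0, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D float array indexed ``(z, y, x)``.  Intensities are HU-like
        scalars (DICOM rescale slope/intercept already applied).
    spacing_mm:
        ``(slice, row, col)`` spacing in millimetres, all strictly positive.
    origin:
        Physical offset of voxel ``(0, 0, 0)``; informational only.
    source_id:
        Provenance string (file path, phantom spec digest, ...).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        nz, ny, nx = self.data.shape
        if nz < 1 or ny < 8 or nx < 8:
            raise ValueError(
                f"volume needs >=1 slice and >=8x8 in-plane extent, got {self.data.shape}"
            )
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A 3D boolean grid on the same lattice as a companion :class:`CTVolume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    role: str = "liver"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.role not in MaskRole:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MaskRole}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def with_data(self, data: np.ndarray, role: str | None = None) -> "BinaryMask":
        """A new mask on the same lattice with different voxel content."""
        return BinaryMask(data=data, spacing_mm=self.spacing_mm, role=role or self.role)

    def same_lattice_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)


def require_same_lattice(*grids) -> None:
    """Raise ``ValueError`` unless all volumes/masks share shape and spacing."""
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape or not np.allclose(g.spacing_mm, first.spacing_mm):
            raise ValueError(
                "lattice mismatch: "
                f"{first.shape}@{first.spacing_mm} vs {g.shape}@{g.spacing_mm}"
            )


def voxel_volume_mm3(v) -> float:
    """Physical volume of one voxel: the product of the three spacing components."""
    s = v.spacing_mm if hasattr(v, "spacing_mm") else v
    s = _check_spacing(s)
    return float(s[0] * s[1] * s[2])
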