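"""CT volume container, grid geometry, and NIfTI/DICOM input-output.

Conventions used throughout the package:

* voxel indices are 0-based; the physical coordinate of voxel ``(i, j, k)``
  is ``origin + (i*dx, j*dy, k*dz)`` (voxel-centre convention);
* the first two array axes are the in-plane axes, the third axis is the
  slice (z) axis — all 2-D operations (gradients, per-slice metrics) act on
  axes 0 and 1;
* intensities are Hounsfield units (HU); air is ``AIR_HU = -1000``;
* NIfTI-1 is the canonical interchange format; DICOM series are read-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

AIR_HU: float = -1000.0

__all__ = [
    "AIR_HU",
    "GridGeometry",
    "CTVolume",
    "GeometryError",
    "FormatError",
    "in_plane_voxel_size",
    "read_volume",
    "write_volume",
]


class GeometryError(ValueError):
    """Inconsistent or physically impossible grid geometry."""


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular axial voxel grid in physical (mm) coordinates.

    Parameters
    ----------
    matrix_size
        In-plane matrix ``(nx, ny)``; 512 x 512 for the reconstructions
        this package models.
    n_slices
        Number of axial slices.
    in_plane_spacing
        Voxel size ``(dx, dy)`` in mm.
    slice_spacing
        Slice increment in mm.
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    matrix_size: tuple[int, int]
    n_slices: int
    in_plane_spacing: tuple[float, float]
    slice_spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        nx, ny = self.matrix_size
        if nx < 2 or ny < 2:
            raise GeometryError(f"matrix sizes must be >= 2, got {self.matrix_size}")
        if self.n_slices < 1:
            raise GeometryError("n_slices must be >= 1")
        dx, dy = self.in_plane_spacing
        if dx <= 0 or dy <= 0 or self.slice_spacing <= 0:
            raise GeometryError("all spacings must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (*self.matrix_size, self.n_slices)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (*self.in_plane_spacing, self.slice_spacing)

    @property
    def fov_diameter(self) -> float:
        """FOV diameter in mm (``nx * dx``; meaningful for square isotropic grids)."""
        return self.matrix_size[0] * self.in_plane_spacing[0]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical centre coordinates of all voxels along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    @classmethod
    def from_fov(
        cls,
        fov_diameter: float,
        matrix: int,
        n_slices: int,
        slice_spacing: float,
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "GridGeometry":
        """Build a square isotropic grid of given FOV centred on ``center``."""
        d = in_plane_voxel_size(fov_diameter, matrix)
        origin = (
            center[0] - d * (matrix - 1) / 2.0,
            center[1] - d * (matrix - 1) / 2.0,
            center[2] - slice_spacing * (n_slices - 1) / 2.0,
        )
        return cls((matrix, matrix), n_slices, (d, d), slice_spacing, origin)


@dataclass
class CTVolume:
    """A 3-D HU-valued scalar field on a :class:`GridGeometry`.

    ``valid`` optionally marks voxels carrying real data (resampling fills
    out-of-extent voxels with air and marks them invalid).
    """

    values: np.ndarray
    geometry: GridGeometry
    identifier: str = ""
    valid: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"value array shape {self.values.shape} != geometry shape "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        if self.valid is not None and self.valid.shape != self.values.shape:
            raise GeometryError("validity mask shape mismatch")

    @property
    def n_slices(self) -> int:
        return self.geometry.n_slices

    def slice(self, k: int) -> np.ndarray:
        return self.values[:, :, k]

    def with_values(self, values: np.ndarray, identifier: str | None = None) -> "CTVolume":
        return CTVolume(values, self.geometry, identifier or self.identifier, self.valid)


def in_plane_voxel_size(fov_diameter: float, matrix: int) -> float:
    """In-plane voxel size (mm) of a reconstruction: ``fov_diameter / matrix``.

    With the matrix fixed at 512, a two-leg FOV of ~423 mm gives ~0.83 mm
    voxels while a single-leg FOV of ~220 mm gives ~0.43 mm voxels — the
    resolution gain the sharpness metric quantifies.
    """
    if fov_diameter <= 0:
        raise ValueError("fov_diameter must be > 0")
    if matrix < 1:
        raise ValueError("matrix must be >= 1")
    return fov_diameter / matrix


def _affine_from_geometry(geom: GridGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = geom.spacing
    aff[:3, 3] = geom.origin
    return aff


def write_volume(vol: CTVolume, path: str | Path, format: str = "nifti") -> None:
    """Write a volume to disk (NIfTI-1, float32)."""
    import nibabel as nib

    if format != "nifti":
        raise FormatError(f"unsupported write format {format!r}")
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine_from_geometry(vol.geometry))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume with physical geometry.

    ``format`` is ``"nifti"`` or ``"dicom-series"`` (a directory of single-frame
    axial files); inferred from the path when omitted.
    """
    path = Path(path)
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise FormatError(f"unknown format {format!r}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    aff = img.affine
    # only axis-aligned affines are supported (no gantry tilt / oblique grids)
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise GeometryError("non-axis-aligned NIfTI affine is not supported")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise GeometryError("non-positive spacing in affine")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got shape {data.shape}")
    geom = GridGeometry(
        matrix_size=(data.shape[0], data.shape[1]),
        n_slices=data.shape[2],
        in_plane_spacing=(float(spacing[0]), float(spacing[1])),
        slice_spacing=float(spacing[2]),
        origin=tuple(float(v) for v in aff[:3, 3]),
    )
    return CTVolume(data, geom, identifier=path.name)


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no files in DICOM directory {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"cannot read DICOM file {f}: {exc}") from exc
        slices.append(ds)

    def key(ds):
        return float(ds.ImagePositionPatient[2])

    slices.sort(key=key)
    first = slices[0]
    spacing = tuple(float(v) for v in first.PixelSpacing)
    rows, cols = int(first.Rows), int(first.Columns)
    for ds in slices[1:]:
        if tuple(float(v) for v in ds.PixelSpacing) != spacing:
            raise GeometryError("heterogeneous PixelSpacing across series")
        if (int(ds.Rows), int(ds.Columns)) != (rows, cols):
            raise GeometryError("heterogeneous matrix size across series")
    z = np.array([key(ds) for ds in slices])
    if len(z) > 1:
        dz = np.diff(z)
        if np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3):
            raise GeometryError("non-uniform slice positions in series")
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0) or 1.0)
    vol = np.empty((rows, cols, len(slices)), dtype=np.float64)
    for k, ds in enumerate(slices):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        vol[:, :, k] = arr * slope + inter
    ipp = first.ImagePositionPatient
    geom = GridGeometry(
        matrix_size=(rows, cols),
        n_slices=len(slices),
        in_plane_spacing=spacing,
        slice_spacing=slice_spacing,
        origin=(float(ipp[0]), float(ipp[1]), float(z[0])),
    )
    return CTVolume(vol, geom, identifier=path.name)
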