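"""Dose-grid data structures, geometry handling, resampling and file I/O.

Conventions
-----------
* Grid values are indexed ``values[ix, iy, iz]`` with axes ordered (x, y, z)
  in patient coordinates; only axis-aligned grids are supported.
* ``origin`` is the physical position (mm) of the *center* of voxel
  ``(0, 0, 0)``; ``spacing`` is the per-axis voxel pitch in mm.
* Doses are stored in Gy and must be finite and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import EmptyGridError, GeometryError, ParameterError
from . import _nrrd, _dicomrt

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "StructureMask",
    "resample_onto",
    "fractional_mask",
    "read_rtdose",
    "write_rtdose",
    "read_nrrd",
    "write_nrrd",
    "read_mask_nrrd",
    "write_mask_nrrd",
]


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned grid geometry: voxel-center origin, spacing and shape."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise GeometryError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing) or not all(np.isfinite(self.spacing)):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(n) <= 0 or int(n) != n for n in self.shape):
            raise GeometryError(f"shape must be positive integers, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            np.allclose(self.origin, other.origin, atol=1e-9)
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and self.shape == other.shape
        )

    def __hash__(self) -> int:  # allclose-based __eq__ keeps exact-tuple hash
        return hash((self.origin, self.spacing, self.shape))


@dataclass(frozen=True)
class DoseGrid:
    """A 3D scalar dose field (Gy) on an axis-aligned grid."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise GeometryError(f"dose values must be 3D, got ndim={values.ndim}")
        if values.shape != self.geometry.shape:
            raise GeometryError(
                f"values shape {values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise GeometryError("dose values must be finite")
        if np.any(values < 0):
            raise GeometryError("dose values must be non-negative")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        origin: tuple[float, float, float],
        spacing: tuple[float, float, float],
    ) -> "DoseGrid":
        values = np.asarray(values, dtype=np.float64)
        return cls(values, GridGeometry(tuple(origin), tuple(spacing), values.shape))

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.geometry.origin

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.geometry.shape

    def max(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class StructureMask:
    """A boolean voxel mask sharing its geometry with an associated DoseGrid."""

    values: np.ndarray
    geometry: GridGeometry
    role: str = "target"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        if values.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {values.shape} != geometry shape {self.geometry.shape}"
            )
        object.__setattr__(self, "values", values)

    def count(self) -> int:
        return int(self.values.sum())


def resample_onto(
    moving: DoseGrid, target_geometry: GridGeometry
) -> tuple[DoseGrid, np.ndarray]:
    """Trilinearly resample ``moving`` at the voxel centers of ``target_geometry``.

    Points outside the support of the moving grid (beyond the outermost voxel
    centers) are filled with 0 and flagged in the returned boolean
    out-of-support mask (True = outside).

    Returns
    -------
    (resampled grid, out_of_support mask)
    """
    tg = target_geometry
    # fractional voxel indices of the target centers on the moving grid
    axes = [
        (tg.voxel_centers(a) - moving.origin[a]) / moving.spacing[a] for a in range(3)
    ]
    idx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([i.ravel() for i in idx])

    out = np.zeros(coords.shape[1], dtype=bool)
    for a in range(3):
        out |= (coords[a] < 0) | (coords[a] > moving.shape[a] - 1)
    vals = map_coordinates(moving.values, coords, order=1, mode="nearest")
    vals[out] = 0.0
    vals = np.clip(vals, 0.0, None)  # guard interpolation round-off
    return (
        DoseGrid(vals.reshape(tg.shape), tg),
        out.reshape(tg.shape),
    )


def fractional_mask(ref: DoseGrid, fraction: float, role: str = "threshold") -> StructureMask:
    """Mask of voxels with dose >= ``fraction`` x max(ref).

    ``fraction`` must lie in (0, 1); an all-zero grid has no meaningful
    maximum and raises :class:`EmptyGridError`.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    dmax = ref.max()
    if dmax <= 0:
        raise EmptyGridError("cannot threshold an all-zero dose grid")
    return StructureMask(ref.values >= fraction * dmax, ref.geometry, role=role)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RTDOSE file into a :class:`DoseGrid` (values in Gy)."""
    values, origin, spacing = _dicomrt.read_rtdose_arrays(Path(path))
    return DoseGrid.from_arrays(values, origin, spacing)


def write_rtdose(grid: DoseGrid, path: str | Path) -> None:
    """Write a :class:`DoseGrid` as a DICOM RTDOSE file (32-bit scaled ints)."""
    _dicomrt.write_rtdose_arrays(grid.values, grid.origin, grid.spacing, Path(path))


def read_nrrd(path: str | Path) -> DoseGrid:
    values, origin, spacing = _nrrd.read(Path(path))
    return DoseGrid.from_arrays(values, origin, spacing)


def write_nrrd(grid: DoseGrid, path: str | Path, encoding: str = "raw") -> None:
    _nrrd.write(Path(path), grid.values, grid.origin, grid.spacing, encoding=encoding)


def read_mask_nrrd(path: str | Path, role: str = "target") -> StructureMask:
    values, origin, spacing = _nrrd.read(Path(path))
    geom = GridGeometry(tuple(origin), tuple(spacing), values.shape)
    return StructureMask(values > 0.5, geom, role=role)


def write_mask_nrrd(mask: StructureMask, path: str | Path, encoding: str = "raw") -> None:
    _nrrd.write(
        Path(path),
        mask.values.astype(np.uint8),
        mask.geometry.origin,
        mask.geometry.spacing,
        encoding=encoding,
    )
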