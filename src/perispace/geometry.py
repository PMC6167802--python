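"""Voxel-grid data model and low-level geometric primitives.

All quantities live on a regular, axis-aligned 3D lattice in LPS patient
coordinates: x increases toward the patient's LEFT, y toward POSTERIOR and
z toward SUPERIOR.  An axial slice is therefore a fixed-z plane, and the
anterior-posterior direction used for surface probing is the y axis.

The voxel center of index ``(i, j, k)`` (0-based) sits at
``origin + (i*sx, j*sy, k*sz)``.  Structure surfaces are located at
occupied-voxel faces (center +/- half a voxel), with no sub-voxel
interpolation, so every geometric result is deterministic and testable
against exhaustive per-voxel oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GeometryError",
    "EmptyStructureError",
    "OutOfBoundsError",
    "CentralRayUndefinedError",
    "GridMismatchError",
    "VolumeGrid",
    "StructureMask",
    "DoseGrid",
    "AnatomicFrame",
    "center_of_mass",
    "volume_cc",
    "directed_surface_y",
    "anatomic_frame",
]


class GeometryError(ValueError):
    """Base class for geometric contract violations."""


class EmptyStructureError(GeometryError):
    """An operation that requires occupied voxels met an empty mask."""


class OutOfBoundsError(GeometryError):
    """A probe point fell outside the voxel lattice."""


class CentralRayUndefinedError(GeometryError):
    """The A-P ray at the CTV center missed the CTV or rectum contour."""


class GridMismatchError(GeometryError):
    """Two volumes that must share one lattice do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3D voxel lattice with patient-space metadata.

    Parameters
    ----------
    dims
        Number of voxels along (x, y, z); each >= 1.
    spacing
        Voxel pitch in mm along (x, y, z); each > 0.
    origin
        Patient-space mm coordinate of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise GeometryError("dims, spacing and origin must be length-3")
        if any(d < 1 for d in self.dims):
            raise GeometryError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_mm(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (0=x, 1=y, 2=z)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def index_to_mm(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(self.spacing) * np.asarray(index)

    def nearest_index(self, value_mm: float, axis: int) -> int:
        """Index of the voxel center nearest to ``value_mm`` along ``axis``.

        Raises
        ------
        OutOfBoundsError
            If the point lies outside the lattice extent (beyond the outer
            voxel faces).
        """
        idx = int(round((value_mm - self.origin[axis]) / self.spacing[axis]))
        if idx < 0 or idx >= self.dims[axis]:
            raise OutOfBoundsError(
                f"coordinate {value_mm} mm outside grid on axis {axis} "
                f"(dims {self.dims}, spacing {self.spacing}, origin {self.origin})"
            )
        return idx

    def column_index(self, x_mm: float, z_mm: float) -> tuple[int, int]:
        """(i, k) of the A-P voxel column nearest to the (x, z) point."""
        return self.nearest_index(x_mm, 0), self.nearest_index(z_mm, 2)


def _check_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if a != b:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


@dataclass
class StructureMask:
    """Binary occupancy of one contoured structure on a grid.

    An empty mask is legal only for the hydrogel (meaning "no gel
    present"); the CTV and rectum must be non-empty wherever an operation
    requires them.
    """

    grid: VolumeGrid
    label: str
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.grid.dims:
            raise GeometryError(
                f"mask shape {self.voxels.shape} does not match grid dims {self.grid.dims}"
            )
        self.voxels = self.voxels.astype(bool)

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def occupied_indices(self) -> np.ndarray:
        """(n, 3) integer array of occupied voxel indices."""
        return np.argwhere(self.voxels)


@dataclass
class DoseGrid:
    """Absorbed dose in cGy per voxel, co-registered with the masks."""

    grid: VolumeGrid
    dose: np.ndarray = field(repr=False)
    prescription: float = 3625.0

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.dims:
            raise GeometryError(
                f"dose shape {self.dose.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise GeometryError("dose must be finite everywhere")
        if np.any(self.dose < 0):
            raise GeometryError("dose must be non-negative everywhere")
        if not self.prescription > 0:
            raise GeometryError("prescription must be > 0")


@dataclass(frozen=True)
class AnatomicFrame:
    """Patient-specific reference frame for placement measurements.

    ``midline_x``/``midgland_z`` are the x and z components of the CTV
    center of mass (prostate midline and midgland).  ``p_point`` is the
    posterior CTV surface point on the central A-P ray, ``r_point`` the
    anterior rectal wall point on the same ray.
    """

    ctv_com: tuple[float, float, float]
    p_point: tuple[float, float, float]
    r_point: tuple[float, float, float]

    @property
    def midline_x(self) -> float:
        return self.ctv_com[0]

    @property
    def midgland_z(self) -> float:
        return self.ctv_com[2]

    def __post_init__(self) -> None:
        if self.p_point[1] > self.r_point[1]:
            raise GeometryError(
                "posterior CTV point lies posterior to the anterior rectal wall "
                f"(P.y={self.p_point[1]:.2f} > R.y={self.r_point[1]:.2f})"
            )


def center_of_mass(mask: StructureMask) -> np.ndarray:
    """Unweighted mean of occupied voxel centers, in patient mm.

    Contours carry no intensity, so occupancy is binary and the mean is
    unweighted.
    """
    if mask.is_empty:
        raise EmptyStructureError(f"empty structure: {mask.label}")
    idx = mask.occupied_indices().mean(axis=0)
    return np.asarray(mask.grid.origin) + np.asarray(mask.grid.spacing) * idx


def volume_cc(mask: StructureMask) -> float:
    """Occupied-voxel count times voxel volume, in cc (0 for an empty mask)."""
    return float(mask.voxels.sum()) * mask.grid.voxel_volume_cc


Side = Literal["posterior_most", "anterior_most"]


def directed_surface_y(
    mask: StructureMask, x_mm: float, z_mm: float, side: Side
) -> float | None:
    """Surface y of a structure along the A-P ray nearest to (x, z).

    Casts an anterior-posterior ray through the voxel column nearest to
    ``(x, z)`` and returns the boundary face of the occupied voxel on the
    requested side: ``posterior_most`` gives the posterior face
    (center + sy/2) of the most posterior occupied voxel, ``anterior_most``
    the anterior face (center - sy/2) of the most anterior one.

    Returns ``None`` ("missing") when the ray intersects no occupied voxel;
    raises :class:`OutOfBoundsError` when (x, z) falls outside the grid —
    the two situations are deliberately distinct.
    """
    i, k = mask.grid.column_index(x_mm, z_mm)
    column = mask.voxels[i, :, k]
    occupied = np.flatnonzero(column)
    if occupied.size == 0:
        return None
    sy = mask.grid.spacing[1]
    oy = mask.grid.origin[1]
    if side == "posterior_most":
        return oy + occupied[-1] * sy + sy / 2.0
    if side == "anterior_most":
        return oy + occupied[0] * sy - sy / 2.0
    raise ValueError(f"unknown side {side!r}")


def anatomic_frame(ctv: StructureMask, rectum: StructureMask) -> AnatomicFrame:
    """Build the anatomic frame from the CTV and rectum masks.

    Midline/midgland come from the CTV center of mass; P and R are the
    posterior CTV face and anterior rectal wall on the central A-P ray.
    """
    _check_same_grid(ctv.grid, rectum.grid)
    if ctv.is_empty:
        raise EmptyStructureError("empty structure: CTV")
    if rectum.is_empty:
        raise EmptyStructureError("empty structure: rectum")
    com = center_of_mass(ctv)
    midline_x, midgland_z = float(com[0]), float(com[2])
    p_y = directed_surface_y(ctv, midline_x, midgland_z, "posterior_most")
    r_y = directed_surface_y(rectum, midline_x, midgland_z, "anterior_most")
    if p_y is None:
        raise CentralRayUndefinedError("central A-P ray misses the CTV contour")
    if r_y is None:
        raise CentralRayUndefinedError("central A-P ray misses the rectum contour")
    if r_y < p_y:
        # crossing contours are a contouring artifact; collapse the central
        # gap to zero like every other clamped negative distance
        import logging

        logging.getLogger(__name__).warning(
            "central ray: rectum wall (%.2f mm) anterior to CTV face (%.2f mm); "
            "clamping to zero gap",
            r_y,
            p_y,
        )
        r_y = p_y
    return AnatomicFrame(
        ctv_com=(float(com[0]), float(com[1]), float(com[2])),
        p_point=(midline_x, float(p_y), midgland_z),
        r_point=(midline_x, float(r_y), midgland_z),
    )
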