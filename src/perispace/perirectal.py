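"""Coronal perirectal-space mapping.

The perirectal space — the anterior-posterior gap between the posterior
prostate (CTV) surface and the anterior rectal wall — is sampled on a
4 x 4 cm coronal grid centered on the prostate midgland at midline, in
1 cm steps: up to 25 distances per patient.  Rows index the
superior-inferior offset (+20 mm = superior), columns the left-right
offset (-20 mm = patient right in our sign convention is NOT implied; the
column offset is along +x = patient left).

A cell is *missing* when either contour is absent along its ray (e.g.
beyond the inferior extent of the rectum), which is preserved — never
imputed — and aggregation is complete-case per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AnatomicFrame,
    GeometryError,
    OutOfBoundsError,
    StructureMask,
    anatomic_frame,
    directed_surface_y,
)

__all__ = [
    "ROW_OFFSETS_Z",
    "COL_OFFSETS_X",
    "PerirectalMap",
    "MapSummary",
    "perirectal_distance",
    "build_map",
    "delta_map",
    "summarize_map",
]

logger = logging.getLogger(__name__)

#: Superior-to-inferior row offsets from midgland, mm (superior positive).
ROW_OFFSETS_Z: tuple[float, ...] = (20.0, 10.0, 0.0, -10.0, -20.0)
#: Left-to-right column offsets from midline, mm (along +x).
COL_OFFSETS_X: tuple[float, ...] = (-20.0, -10.0, 0.0, 10.0, 20.0)


@dataclass
class PerirectalMap:
    """5x5 grid of A-P gap distances (mm), NaN marking missing cells."""

    distances: np.ndarray = field(repr=False)
    row_offsets_z: tuple[float, ...] = ROW_OFFSETS_Z
    col_offsets_x: tuple[float, ...] = COL_OFFSETS_X
    frame: AnatomicFrame | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        expected = (len(self.row_offsets_z), len(self.col_offsets_x))
        if self.distances.shape != expected:
            raise GeometryError(
                f"distance array shape {self.distances.shape} != offsets {expected}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.distances < 0):
                raise GeometryError("perirectal distances must be >= 0")

    @property
    def center(self) -> float:
        """The perirectal distance at CTV center (offsets (0, 0)); NaN if missing."""
        r = self.row_offsets_z.index(0.0)
        c = self.col_offsets_x.index(0.0)
        return float(self.distances[r, c])

    @property
    def n_cells(self) -> int:
        return int(np.isfinite(self.distances).sum())


@dataclass(frozen=True)
class MapSummary:
    """Row/column/overall aggregates over the non-missing cells of one map."""

    row_means: tuple[float, ...]
    row_sds: tuple[float, ...]
    col_means: tuple[float, ...]
    col_sds: tuple[float, ...]
    overall_mean: float
    overall_sd: float
    n_cells: int


def perirectal_distance(
    ctv: StructureMask,
    rectum: StructureMask,
    frame: AnatomicFrame,
    dx_mm: float,
    dz_mm: float,
) -> float | None:
    """A-P gap between posterior CTV and anterior rectum at one grid vertex.

    The ray is cast at ``(midline_x + dx, midgland_z + dz)``.  Returns the
    anterior-rectal-wall y minus the posterior-CTV y, or ``None`` when
    either surface is absent along the ray.  A negative gap (crossing
    contours, a contouring artifact) clamps to 0 with a logged warning.
    """
    x = frame.midline_x + dx_mm
    z = frame.midgland_z + dz_mm
    y_ctv = directed_surface_y(ctv, x, z, "posterior_most")
    if y_ctv is None:
        return None
    y_rec = directed_surface_y(rectum, x, z, "anterior_most")
    if y_rec is None:
        return None
    gap = y_rec - y_ctv
    if gap < 0:
        logger.warning(
            "overlapping CTV/rectum contours at offset (%+g, %+g) mm: "
            "gap %.2f mm clamped to 0",
            dx_mm,
            dz_mm,
            gap,
        )
        return 0.0
    return float(gap)


def build_map(ctv: StructureMask, rectum: StructureMask) -> PerirectalMap:
    """Evaluate all 25 grid vertices; absent contours leave cells missing.

    Rays that would leave the voxel lattice are treated like absent
    contours (missing) rather than errors, since the map is defined in
    patient space and the lattice is merely its sampling support.
    """
    frame = anatomic_frame(ctv, rectum)
    distances = np.full((len(ROW_OFFSETS_Z), len(COL_OFFSETS_X)), np.nan)
    for r, dz in enumerate(ROW_OFFSETS_Z):
        for c, dx in enumerate(COL_OFFSETS_X):
            try:
                d = perirectal_distance(ctv, rectum, frame, dx, dz)
            except OutOfBoundsError:
                d = None
            if d is not None:
                distances[r, c] = d
    return PerirectalMap(distances=distances, frame=frame)


def delta_map(pre_map: PerirectalMap, post_map: PerirectalMap) -> PerirectalMap:
    """Cellwise change in perirectal space: post minus pre.

    A positive value is space *created* (e.g. by hydrogel placement).
    Cells missing in either operand stay missing.
    """
    if (
        pre_map.row_offsets_z != post_map.row_offsets_z
        or pre_map.col_offsets_x != post_map.col_offsets_x
    ):
        raise GeometryError("maps have mismatched grid offsets")
    diff = post_map.distances - pre_map.distances
    # A shrinking gap yields a legitimately negative delta; bypass the
    # non-negativity check that applies to raw distance maps.
    out = PerirectalMap.__new__(PerirectalMap)
    out.distances = diff
    out.row_offsets_z = pre_map.row_offsets_z
    out.col_offsets_x = pre_map.col_offsets_x
    out.frame = post_map.frame
    return out


def summarize_map(pmap: PerirectalMap) -> MapSummary:
    """Row/column/overall means and sample SDs over non-missing cells.

    SDs use the n-1 denominator; a row or column with fewer than two
    non-missing cells gets an undefined (NaN) SD, and an entirely missing
    row or column an undefined mean.
    """
    d = pmap.distances
    if not np.isfinite(d).any():
        raise GeometryError("cannot summarize an all-missing map")

    def _mean(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else float("nan")

    def _sd(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        return float(v.std(ddof=1)) if v.size >= 2 else float("nan")

    return MapSummary(
        row_means=tuple(_mean(d[r]) for r in range(d.shape[0])),
        row_sds=tuple(_sd(d[r]) for r in range(d.shape[0])),
        col_means=tuple(_mean(d[:, c]) for c in range(d.shape[1])),
        col_sds=tuple(_sd(d[:, c]) for c in range(d.shape[1])),
        overall_mean=_mean(d.ravel()),
        overall_sd=_sd(d.ravel()),
        n_cells=pmap.n_cells,
    )
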