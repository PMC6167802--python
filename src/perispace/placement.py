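"""Hydrogel placement metrics.

Three quantities score how well a perirectal hydrogel spacer was placed:

* the contoured gel volume (cc);
* the angle theta, with vertex at the gel center of mass G, subtended by
  the posterior-CTV point P at CTV center and the anterior rectal wall
  point R on the same central ray.  Perfect interposition of the gel on
  the P-R segment gives theta = 180 deg; lateral or craniocaudal
  misplacement shrinks it;
* their normalized product (theta/180) * (V / V_ref), where V_ref is by
  default the largest gel volume in the cohort, giving a unitless score
  in [0, ~1] that captures the volume-angle interaction.

A separate categorical rubric scores lateral symmetry on three axial
slices (midgland and +/- 1 cm): SYM1 when the gel is present and within
1 cm of midline on all three, SYM2 when exactly one slice deviates by
1-2 cm, and distinct "missing slice" categories when the gel is absent
from a slice — absence inferiorly being the clinically notable case.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geometry import (
    AnatomicFrame,
    EmptyStructureError,
    GeometryError,
    StructureMask,
    center_of_mass,
    volume_cc,
)

__all__ = [
    "DegenerateAngleError",
    "SymmetryCategory",
    "SliceRecord",
    "SymmetryAssessment",
    "PlacementMetrics",
    "theta",
    "normalized_theta_volume",
    "cohort_reference_volume",
    "symmetry_assessment",
    "compute_placement_metrics",
]

#: Axial slice offsets (mm from midgland) used by the symmetry rubric.
SYMMETRY_SLICE_OFFSETS_Z: tuple[float, ...] = (10.0, 0.0, -10.0)

#: Lateral deviation thresholds (mm): < ASYM is symmetric, [ASYM, SEVERE)
#: is mild asymmetry, >= SEVERE is gross asymmetry.
ASYMMETRY_THRESHOLD_MM = 10.0
SEVERE_ASYMMETRY_THRESHOLD_MM = 20.0

#: Minimum gel cross-section per slice slab (cc) to count as "present";
#: keeps single stray voxels from registering as gel.
PRESENCE_THRESHOLD_CC = 0.05


class DegenerateAngleError(GeometryError):
    """The gel COM coincides with an angle endpoint."""


class SymmetryCategory(str, enum.Enum):
    SYM1 = "SYM1"
    SYM2 = "SYM2"
    SYM3PLUS = "SYM3plus"
    MISSING_INF = "MISSING_INF"
    MISSING_MID = "MISSING_MID"
    MISSING_SUP = "MISSING_SUP"
    MULTI_MISSING = "MULTI_MISSING"


@dataclass(frozen=True)
class SliceRecord:
    """Gel presence and lateral deviation on one axial slice."""

    z_offset_mm: float
    present: bool
    lateral_deviation_mm: float | None


@dataclass(frozen=True)
class SymmetryAssessment:
    per_slice: tuple[SliceRecord, SliceRecord, SliceRecord]
    category: SymmetryCategory


@dataclass(frozen=True)
class PlacementMetrics:
    """Bundle of the per-patient placement quantities."""

    gel_volume_cc: float
    theta_deg: float | None
    norm_theta_vol: float
    gel_com: tuple[float, float, float] | None


def theta(frame: AnatomicFrame, gel: StructureMask) -> float | None:
    """Placement angle in degrees, or ``None`` when no gel is present.

    Vertex at the gel center of mass G; theta is the angle between the
    vectors G->P and G->R via the arccosine of their normalized inner
    product.  Returns a value in [0, 180].
    """
    if gel.is_empty:
        return None
    g = center_of_mass(gel)
    p = np.asarray(frame.p_point, dtype=float)
    r = np.asarray(frame.r_point, dtype=float)
    vp = p - g
    vr = r - g
    np_len = np.linalg.norm(vp)
    nr_len = np.linalg.norm(vr)
    if np_len < 1e-6 or nr_len < 1e-6:
        raise DegenerateAngleError(
            "gel center of mass coincides with an angle endpoint"
        )
    cosang = np.clip(np.dot(vp, vr) / (np_len * nr_len), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def normalized_theta_volume(
    theta_deg: float | None, gel_volume_cc: float, reference_volume_cc: float
) -> float:
    """(theta/180) * (V/V_ref); 0 when theta is undefined (no gel)."""
    if reference_volume_cc <= 0:
        raise ValueError("reference volume must be > 0")
    if theta_deg is None:
        return 0.0
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError(f"theta must lie in [0, 180], got {theta_deg}")
    if gel_volume_cc < 0:
        raise ValueError("gel volume must be >= 0")
    return (theta_deg / 180.0) * (gel_volume_cc / reference_volume_cc)


def cohort_reference_volume(
    volumes_cc: list[float] | tuple[float, ...] | np.ndarray,
    override_cc: float | None = None,
) -> float:
    """Largest contoured gel volume in the cohort, or a fixed override.

    The override supports cross-cohort comparison with a frozen
    normalization constant.
    """
    if override_cc is not None:
        if override_cc <= 0:
            raise ValueError("reference volume override must be > 0")
        return float(override_cc)
    volumes = np.asarray(volumes_cc, dtype=float)
    if volumes.size == 0:
        raise ValueError("need at least one gel volume")
    return float(volumes.max())


def _slice_record(
    frame: AnatomicFrame,
    gel: StructureMask,
    z_offset_mm: float,
    presence_threshold_cc: float,
) -> SliceRecord:
    grid = gel.grid
    try:
        k = grid.nearest_index(frame.midgland_z + z_offset_mm, axis=2)
    except GeometryError:
        return SliceRecord(z_offset_mm, present=False, lateral_deviation_mm=None)
    cross = gel.voxels[:, :, k]
    slab_cc = float(cross.sum()) * grid.voxel_volume_cc
    if slab_cc < presence_threshold_cc:
        return SliceRecord(z_offset_mm, present=False, lateral_deviation_mm=None)
    i_idx = np.nonzero(cross)[0]
    com_x = grid.origin[0] + grid.spacing[0] * float(i_idx.mean())
    deviation = abs(com_x - frame.midline_x)
    return SliceRecord(z_offset_mm, present=True, lateral_deviation_mm=deviation)


def symmetry_assessment(
    frame: AnatomicFrame,
    gel: StructureMask,
    presence_threshold_cc: float = PRESENCE_THRESHOLD_CC,
    asym_mm: float = ASYMMETRY_THRESHOLD_MM,
    severe_mm: float = SEVERE_ASYMMETRY_THRESHOLD_MM,
) -> SymmetryAssessment:
    """Categorical lateral-symmetry score over three axial slices.

    Presence on a slice requires a gel cross-section of at least
    ``presence_threshold_cc`` in that axial slab; the lateral deviation is
    the |x| distance of the in-slice gel centroid from prostate midline.
    """
    if not 0 < asym_mm < severe_mm:
        raise ValueError("thresholds must satisfy 0 < asym < severe")
    records = tuple(
        _slice_record(frame, gel, dz, presence_threshold_cc)
        for dz in SYMMETRY_SLICE_OFFSETS_Z
    )
    absent = [rec for rec in records if not rec.present]
    if len(absent) >= 2:
        category = SymmetryCategory.MULTI_MISSING
    elif len(absent) == 1:
        off = absent[0].z_offset_mm
        if off < 0:
            category = SymmetryCategory.MISSING_INF
        elif off > 0:
            category = SymmetryCategory.MISSING_SUP
        else:
            category = SymmetryCategory.MISSING_MID
    else:
        devs = [rec.lateral_deviation_mm for rec in records]
        n_mild = sum(1 for d in devs if asym_mm <= d < severe_mm)
        n_severe = sum(1 for d in devs if d >= severe_mm)
        if n_severe == 0 and n_mild == 0:
            category = SymmetryCategory.SYM1
        elif n_severe == 0 and n_mild == 1:
            category = SymmetryCategory.SYM2
        else:
            category = SymmetryCategory.SYM3PLUS
    return SymmetryAssessment(per_slice=records, category=category)


def compute_placement_metrics(
    frame: AnatomicFrame,
    gel: StructureMask,
    reference_volume_cc: float,
) -> PlacementMetrics:
    """Volume, theta and normalized theta*volume for one patient.

    Patients without gel stay in cohort analyses with a score of 0 rather
    than erroring out.
    """
    vol = volume_cc(gel)
    if gel.is_empty:
        return PlacementMetrics(
            gel_volume_cc=0.0, theta_deg=None, norm_theta_vol=0.0, gel_com=None
        )
    th = theta(frame, gel)
    com = center_of_mass(gel)
    return PlacementMetrics(
        gel_volume_cc=vol,
        theta_deg=th,
        norm_theta_vol=normalized_theta_volume(th, vol, reference_volume_cc),
        gel_com=(float(com[0]), float(com[1]), float(com[2])),
    )
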