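"""Synthetic prostate/rectum/hydrogel phantoms with a parametric dose model.

Every pipeline stage is testable without patient imaging via phantoms
that emulate the measured anatomy:

* an ellipsoidal prostate CTV of controllable volume (cohort-like
  default 40.1 cc);
* a tubular rectum posterior to it, separated by a small native gap
  (default 2 mm, matching the 1-2 mm native perirectal space measured
  inferomedially in patients);
* a hydrogel "dome" of controllable volume draped on the posterior CTV
  surface, laterally/craniocaudally displaceable from the optimal
  midgland/midline position.  Where the gel interposes, the rectum's
  anterior wall is displaced posteriorly by the local gel thickness —
  the space-creation mechanism, without biomechanics;
* an SBRT-like dose grid: prescription dose inside the PTV (CTV plus an
  anisotropic margin, 5 mm except 3 mm posteriorly per RTOG-0938-style
  convention) decaying exponentially with distance to the PTV surface.
  The falloff (default 8 %/mm) is a configurable geometric surrogate for
  a steep posterior SBRT gradient, not a beam calculation.

Each phantom carries a ground-truth record (planted centers of mass, the
analytic placement angle, the planted gap profile) so parameter-recovery
tests can compare pipeline measurements against known values.

All randomness flows through one seeded generator; the same seed
reproduces a cohort bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import DoseGrid, GeometryError, StructureMask, VolumeGrid
from .perirectal import COL_OFFSETS_X, ROW_OFFSETS_Z

__all__ = [
    "InfeasiblePhantomError",
    "PhantomSpec",
    "CohortSpec",
    "PhantomTruth",
    "StructureSet",
    "make_phantom",
    "sample_cohort",
]


class InfeasiblePhantomError(GeometryError):
    """The requested anatomy does not fit on the voxel lattice."""


#: CTV semi-axis proportions (x, y, z): slightly wider than tall, longest
#: craniocaudally — a generic prostate shape.
_CTV_AXIS_RATIOS = np.array([1.05, 0.80, 1.15])

#: Gel dome aspect: maximum thickness as a fraction of the dome radius.
_GEL_THICKNESS_RATIO = 0.55


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, placement and dose parameters for one phantom."""

    dims: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ctv_volume_cc: float = 40.1
    ctv_rectum_gap_mm: float = 2.0
    rectum_halfwidth_mm: float = 26.0
    rectum_halfdepth_mm: float = 9.0
    rectum_z_margin_mm: float = 8.0
    gel_volume_cc: float = 10.3
    #: displacement of the gel dome from midgland/midline, (dx, dy, dz) mm;
    #: dy > 0 floats the gel posteriorly off the CTV surface.
    gel_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prescription_cgy: float = 3625.0
    ptv_margin_mm: float = 5.0
    ptv_margin_post_mm: float = 3.0
    dose_falloff_per_mm: float = 0.08
    dose_scale: float = 1.0
    ctv_center_y_mm: float = 44.0

    def __post_init__(self) -> None:
        if self.ctv_volume_cc <= 0 or self.gel_volume_cc < 0:
            raise ValueError("ctv volume must be > 0 and gel volume >= 0")
        if self.dose_falloff_per_mm <= 0:
            raise ValueError("dose falloff must be > 0")
        if self.ctv_rectum_gap_mm < 0:
            raise ValueError("native gap must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for a synthetic patient cohort.

    Defaults emulate the clinical cohort conditions: CTV volume
    40.1 +/- 22.5 cc, gel volume 10.3 +/- 4.5 cc.  Placement quality is a
    two-component mixture mimicking the operator learning curve: a
    fraction of near-ideal placements (small offsets from
    midgland/midline) and a dispersed remainder, which together scatter
    the placement angle around roughly 70 +/- 50 degrees.
    """

    n: int = 20
    seed: int = 0
    ctv_volume_mean_cc: float = 40.1
    ctv_volume_sd_cc: float = 22.5
    ctv_volume_bounds_cc: tuple[float, float] = (13.0, 108.0)
    gel_volume_mean_cc: float = 10.3
    gel_volume_sd_cc: float = 4.5
    gel_volume_bounds_cc: tuple[float, float] = (3.0, 22.0)
    well_placed_fraction: float = 0.4
    gel_offset_well_sd_mm: float = 2.0
    gel_offset_poor_sd_mm: float = 12.0
    gel_offset_ap_sd_mm: float = 1.0
    gel_offset_bound_mm: float = 25.0
    dose_noise_sd: float = 0.02
    base: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for sd in (
            self.ctv_volume_sd_cc,
            self.gel_volume_sd_cc,
            self.gel_offset_well_sd_mm,
            self.gel_offset_poor_sd_mm,
            self.gel_offset_ap_sd_mm,
            self.dose_noise_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.well_placed_fraction <= 1.0:
            raise ValueError("well_placed_fraction must lie in [0, 1]")


@dataclass
class StructureSet:
    """Co-registered masks of one phantom patient."""

    grid: VolumeGrid
    ctv: StructureMask
    rectum: StructureMask
    gel: StructureMask
    ptv: StructureMask


@dataclass
class PhantomTruth:
    """Planted (analytic, voxelization-free) ground truth of one phantom."""

    spec: PhantomSpec
    ctv_com: tuple[float, float, float]
    ctv_semiaxes_mm: tuple[float, float, float]
    p_point: tuple[float, float, float]
    r_point: tuple[float, float, float]
    gel_com: tuple[float, float, float] | None
    gel_volume_cc: float
    theta_deg: float | None
    central_displacement_mm: float
    #: analytic perirectal gap at the 5x5 map offsets (NaN where undefined)
    gap_map_mm: np.ndarray = field(repr=False, default=None)


def _ctv_semiaxes(volume_cc: float) -> np.ndarray:
    """Semi-axes (mm) of an ellipsoid with the requested volume."""
    target_mm3 = volume_cc * 1000.0
    scale = (3.0 * target_mm3 / (4.0 * np.pi * np.prod(_CTV_AXIS_RATIOS))) ** (1.0 / 3.0)
    return _CTV_AXIS_RATIOS * scale


def _gel_dome(volume_cc: float) -> tuple[float, float]:
    """(footprint radius, max thickness) in mm of the hemispherical-profile dome.

    Thickness profile t(r) = t_max * sqrt(1 - (r/R)^2) integrates to
    (2 pi / 3) R^2 t_max; the aspect t_max = 0.55 R is fixed, so volume
    alone determines both numbers.
    """
    if volume_cc <= 0:
        return 0.0, 0.0
    v_mm3 = volume_cc * 1000.0
    radius = (3.0 * v_mm3 / (2.0 * np.pi * _GEL_THICKNESS_RATIO)) ** (1.0 / 3.0)
    return radius, _GEL_THICKNESS_RATIO * radius


def _angle_deg(g: np.ndarray, p: np.ndarray, r: np.ndarray) -> float:
    vp, vr = p - g, r - g
    c = np.dot(vp, vr) / (np.linalg.norm(vp) * np.linalg.norm(vr))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def make_phantom(spec: PhantomSpec) -> tuple[StructureSet, DoseGrid, PhantomTruth]:
    """Build one phantom patient: masks, dose and ground truth.

    Raises :class:`InfeasiblePhantomError` when the displaced rectum or
    the gel would run off the voxel lattice (a gel too large for the
    requested placement).
    """
    grid = VolumeGrid(dims=spec.dims, spacing=spec.spacing)
    nx, ny, nz = grid.dims
    X = grid.axis_mm(0)
    Y = grid.axis_mm(1)
    Z = grid.axis_mm(2)
    cx = float(X.mean())
    cz = float(Z.mean())
    cy = spec.ctv_center_y_mm

    a, b, c = _ctv_semiaxes(spec.ctv_volume_cc)

    # --- analytic column surfaces over the (x, z) plane -------------------
    Xc = (X[:, None] - cx)
    Zc = (Z[None, :] - cz)
    ellipse = (Xc / a) ** 2 + (Zc / c) ** 2          # CTV footprint term
    in_ctv_footprint = ellipse < 1.0
    # posterior CTV face; flat at the equator level outside the footprint so
    # gel columns beyond the prostate edge wrap smoothly instead of jumping
    face = cy + b * np.sqrt(np.clip(1.0 - ellipse, 0.0, None))

    # pre-gel rectum anterior wall
    gap0 = spec.ctv_rectum_gap_mm
    half_w = spec.rectum_halfwidth_mm
    half_d = spec.rectum_halfdepth_mm
    y_rect_center = cy + b + gap0 + half_d
    lat = np.abs(X[:, None] - cx) / half_w
    in_rect_x = lat < 1.0
    rect_half_depth = half_d * np.sqrt(np.clip(1.0 - lat**2, 0.0, None))
    z_lo = cz - c - spec.rectum_z_margin_mm
    z_hi = cz + c + spec.rectum_z_margin_mm
    in_rect_z = (Z[None, :] >= z_lo) & (Z[None, :] <= z_hi)
    in_rect_footprint = in_rect_x & in_rect_z
    wall0 = np.where(in_rect_footprint, y_rect_center - rect_half_depth, np.nan)

    # gel dome thickness profile around the displaced dome center
    offx, offy, offz = spec.gel_offset_mm
    gel_radius, t_max = _gel_dome(spec.gel_volume_cc)
    if gel_radius > 0:
        u = ((X[:, None] - (cx + offx)) / gel_radius) ** 2 + (
            (Z[None, :] - (cz + offz)) / gel_radius
        ) ** 2
        thickness = t_max * np.sqrt(np.clip(1.0 - u, 0.0, None))
    else:
        thickness = np.zeros((nx, nz))
    clearance = max(0.5 * grid.spacing[1], gap0 / 2.0 + offy)
    gel_lo = face + clearance
    gel_hi = gel_lo + thickness

    # rectum displaced posteriorly wherever the gel interposes
    displacement = np.where(
        in_rect_footprint & (thickness > 0),
        np.clip(gel_hi - wall0, 0.0, None),
        0.0,
    )
    wall = wall0 + displacement

    y_max_needed = np.nanmax(
        np.where(in_rect_footprint, wall + 2.0 * rect_half_depth, np.nan)
    )
    if thickness.max() > 0:
        y_max_needed = max(y_max_needed, float(gel_hi[thickness > 0].max()))
    if y_max_needed > Y[-1] or cy - b < Y[0]:
        raise InfeasiblePhantomError(
            f"anatomy extends to y={y_max_needed:.1f} mm, beyond the "
            f"{Y[-1]:.1f} mm lattice: gel too large for this placement"
        )

    # --- voxelization ------------------------------------------------------
    Yb = Y[None, :, None]
    ell3 = (
        ((X[:, None, None] - cx) / a) ** 2
        + ((Yb - cy) / b) ** 2
        + ((Z[None, None, :] - cz) / c) ** 2
    )
    ctv_vox = ell3 <= 1.0

    rect_lo = wall[:, None, :]
    rect_hi = (wall + 2.0 * rect_half_depth)[:, None, :]
    with np.errstate(invalid="ignore"):
        rectum_vox = (Yb >= rect_lo) & (Yb <= rect_hi)
    rectum_vox &= in_rect_footprint[:, None, :]

    gel_vox = (Yb >= gel_lo[:, None, :]) & (Yb < gel_hi[:, None, :])
    gel_vox &= ~ctv_vox & ~rectum_vox

    # --- dose model --------------------------------------------------------
    dist_ctv = ndimage.distance_transform_edt(~ctv_vox, sampling=grid.spacing)
    posterior = in_ctv_footprint[:, None, :] & (Yb > face[:, None, :])
    margin = np.where(posterior, spec.ptv_margin_post_mm, spec.ptv_margin_mm)
    ptv_vox = dist_ctv <= margin
    dist_ptv = ndimage.distance_transform_edt(~ptv_vox, sampling=grid.spacing)
    dose = (
        spec.dose_scale
        * spec.prescription_cgy
        * np.exp(-spec.dose_falloff_per_mm * dist_ptv)
    )

    structures = StructureSet(
        grid=grid,
        ctv=StructureMask(grid, "CTV", ctv_vox),
        rectum=StructureMask(grid, "rectum", rectum_vox),
        gel=StructureMask(grid, "hydrogel", gel_vox),
        ptv=StructureMask(grid, "PTV", ptv_vox),
    )
    dose_grid = DoseGrid(grid, dose, prescription=spec.prescription_cgy)

    # --- planted ground truth ----------------------------------------------
    # P and R describe the phantom as realized on the lattice: the central
    # A-P column's voxel faces (the analytic target surfaces differ by at
    # most half a voxel).  The gel COM stays analytic (dome integral), so
    # recovery tests compare an independent quantity.
    i_c, k_c = grid.column_index(cx, cz)
    sy = grid.spacing[1]
    ctv_col = np.flatnonzero(ctv_vox[i_c, :, k_c])
    rect_col = np.flatnonzero(rectum_vox[i_c, :, k_c])
    p_y = Y[ctv_col[-1]] + sy / 2.0 if ctv_col.size else cy + b
    r_y = Y[rect_col[0]] - sy / 2.0 if rect_col.size else float(wall[i_c, k_c])
    p_true = np.array([cx, p_y, cz])
    r_true = np.array([cx, max(r_y, p_y), cz])
    d_center = float(displacement[i_c, k_c])

    if spec.gel_volume_cc > 0:
        dx, dz_sp = grid.spacing[0], grid.spacing[2]
        w = thickness * dx * dz_sp
        total = w.sum()
        gel_com = np.array(
            [
                (X[:, None] * w).sum() / total,
                (((gel_lo + gel_hi) / 2.0) * w).sum() / total,
                (Z[None, :] * w).sum() / total,
            ]
        )
        theta_true = _angle_deg(gel_com, p_true, r_true)
        gel_com_t = tuple(map(float, gel_com))
        gel_vol_true = float(total) / 1000.0
    else:
        gel_com_t = None
        theta_true = None
        gel_vol_true = 0.0

    gap_map = np.full((len(ROW_OFFSETS_Z), len(COL_OFFSETS_X)), np.nan)
    for ri, dzo in enumerate(ROW_OFFSETS_Z):
        for ci, dxo in enumerate(COL_OFFSETS_X):
            xq, zq = cx + dxo, cz + dzo
            iq = int(round((xq - grid.origin[0]) / grid.spacing[0]))
            kq = int(round((zq - grid.origin[2]) / grid.spacing[2]))
            if not (0 <= iq < nx and 0 <= kq < nz):
                continue
            if in_ctv_footprint[iq, kq] and in_rect_footprint[iq, kq]:
                gap_map[ri, ci] = wall[iq, kq] - face[iq, kq]

    truth = PhantomTruth(
        spec=spec,
        ctv_com=(cx, cy, cz),
        ctv_semiaxes_mm=(float(a), float(b), float(c)),
        p_point=tuple(map(float, p_true)),
        r_point=tuple(map(float, r_true)),
        gel_com=gel_com_t,
        gel_volume_cc=gel_vol_true,
        theta_deg=theta_true,
        central_displacement_mm=d_center,
        gap_map_mm=gap_map,
    )
    return structures, dose_grid, truth


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection-sampled truncated normal (exact, seed-reproducible)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError("truncated-normal sampling failed; check bounds")


def sample_cohort(
    spec: CohortSpec,
) -> list[tuple[PhantomSpec, StructureSet, DoseGrid, PhantomTruth]]:
    """Sample and build a reproducible cohort of phantom patients.

    Volumes and offsets come from truncated normal distributions;
    infeasible draws (gel too large for the sampled placement) are
    redrawn up to a bounded retry count.
    """
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for _ in range(spec.n):
        for attempt in range(20):
            bound = spec.gel_offset_bound_mm
            offset_sd = (
                spec.gel_offset_well_sd_mm
                if rng.random() < spec.well_placed_fraction
                else spec.gel_offset_poor_sd_mm
            )
            pspec = replace(
                spec.base,
                ctv_volume_cc=_truncated_normal(
                    rng,
                    spec.ctv_volume_mean_cc,
                    spec.ctv_volume_sd_cc,
                    *spec.ctv_volume_bounds_cc,
                ),
                gel_volume_cc=_truncated_normal(
                    rng,
                    spec.gel_volume_mean_cc,
                    spec.gel_volume_sd_cc,
                    *spec.gel_volume_bounds_cc,
                ),
                gel_offset_mm=(
                    _truncated_normal(rng, 0.0, offset_sd, -bound, bound),
                    _truncated_normal(
                        rng, 0.0, spec.gel_offset_ap_sd_mm, -3.0, 3.0
                    ),
                    _truncated_normal(rng, 0.0, offset_sd, -bound, bound),
                ),
                dose_scale=float(
                    np.clip(1.0 + spec.dose_noise_sd * rng.standard_normal(), 0.8, 1.2)
                ),
            )
            try:
                structures, dose, truth = make_phantom(pspec)
            except InfeasiblePhantomError:
                continue
            cohort.append((pspec, structures, dose, truth))
            break
        else:
            raise InfeasiblePhantomError(
                "could not sample a feasible phantom in 20 attempts"
            )
    return cohort
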