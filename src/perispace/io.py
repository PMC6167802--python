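"""File formats: volumes (NIfTI and a plain JSON format), maps, reports.

Volumes travel either as NIfTI (one file per structure; the affine is
restricted to axis-aligned positive scaling, and its translation/scaling
are interpreted directly in the package's LPS mm frame) or as a plain
JSON format — a header with dims/spacing/origin/label plus the flattened
voxel array — which keeps test fixtures human-readable and diffable.

Missing values are serialized as ``NA`` in CSV and ``null`` in JSON.
Distances are printed to 0.1 mm, doses to 1 cGy and R-squared values to
2 decimals.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import BatteryReport
from .geometry import DoseGrid, GeometryError, StructureMask, VolumeGrid
from .perirectal import COL_OFFSETS_X, ROW_OFFSETS_Z, MapSummary, PerirectalMap
from .pipeline import PatientRecord, RunConfig

__all__ = [
    "UnsupportedGeometryError",
    "read_volume",
    "write_mask",
    "write_dose",
    "write_map_csv",
    "read_map_csv",
    "write_map_json",
    "patient_record_json",
    "write_report",
    "write_dvh_csv",
    "load_run_config",
]

PLAIN_FORMAT_NAME = "perispace-volume"


class UnsupportedGeometryError(GeometryError):
    """The file's geometry (e.g. an oblique affine) is not supported."""


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VolumeGrid:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6:
        raise UnsupportedGeometryError(
            "oblique or rotated affine; only axis-aligned scaling is supported"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise UnsupportedGeometryError(
            f"affine must have positive diagonal scaling, got {spacing}"
        )
    return VolumeGrid(
        dims=tuple(int(s) for s in shape),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in affine[:3, 3]),
    )


def _affine_from_grid(grid: VolumeGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _load_array(path: Path) -> tuple[VolumeGrid, np.ndarray, dict]:
    if _is_nifti(path):
        img = nib.load(str(path))
        grid = _grid_from_affine(np.asarray(img.affine), img.shape)
        data = np.asarray(img.dataobj, dtype=float)
        meta: dict = {}
    else:
        payload = json.loads(path.read_text())
        if payload.get("format") != PLAIN_FORMAT_NAME:
            raise GeometryError(f"{path} is not a {PLAIN_FORMAT_NAME} file")
        grid = VolumeGrid(
            dims=tuple(payload["dims"]),
            spacing=tuple(payload["spacing"]),
            origin=tuple(payload.get("origin", (0.0, 0.0, 0.0))),
        )
        data = np.asarray(payload["data"], dtype=float).reshape(grid.dims)
        meta = {k: payload[k] for k in ("label", "kind", "prescription") if k in payload}
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return grid, data, meta


def read_volume(
    path: str | Path,
    kind: str = "mask",
    label: str | None = None,
    prescription: float = 3625.0,
) -> StructureMask | DoseGrid:
    """Read a mask or dose volume from NIfTI or the plain JSON format.

    Masks tolerate the common {0, 255} byte dialect (normalized to {0, 1}
    with a warning); any other non-binary payload is rejected.  Dose
    volumes must be finite and non-negative.
    """
    path = Path(path)
    grid, data, meta = _load_array(path)
    kind = meta.get("kind", kind)
    if kind == "mask":
        values = np.unique(data)
        if set(values.tolist()) <= {0.0, 1.0}:
            voxels = data > 0.5
        elif set(values.tolist()) <= {0.0, 255.0}:
            warnings.warn(
                f"{path.name}: mask encoded as {{0, 255}}; normalizing to {{0, 1}}",
                stacklevel=2,
            )
            voxels = data > 127
        else:
            raise GeometryError(
                f"{path.name}: mask values must be binary, found {values[:8]}"
            )
        return StructureMask(grid, label or meta.get("label", path.stem), voxels)
    if kind == "dose":
        if np.any(data < 0):
            raise GeometryError(f"{path.name}: dose contains negative voxels")
        return DoseGrid(grid, data, prescription=meta.get("prescription", prescription))
    raise ValueError(f"unknown volume kind {kind!r}")


def _write_plain(path: Path, grid: VolumeGrid, data: np.ndarray, **meta) -> None:
    payload = {
        "format": PLAIN_FORMAT_NAME,
        "dims": list(grid.dims),
        "spacing": list(grid.spacing),
        "origin": list(grid.origin),
        **meta,
        "data": data.ravel(order="C").tolist(),
    }
    path.write_text(json.dumps(payload))


def write_mask(mask: StructureMask, path: str | Path) -> None:
    """Write a binary mask as NIfTI (.nii/.nii.gz) or plain JSON (.json)."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.Nifti1Image(
            mask.voxels.astype(np.uint8), _affine_from_grid(mask.grid)
        )
        nib.save(img, str(path))
    else:
        _write_plain(
            path,
            mask.grid,
            mask.voxels.astype(int),
            kind="mask",
            label=mask.label,
        )


def write_dose(dose: DoseGrid, path: str | Path) -> None:
    """Write a dose grid as NIfTI or plain JSON."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.Nifti1Image(
            dose.dose.astype(np.float32), _affine_from_grid(dose.grid)
        )
        nib.save(img, str(path))
    else:
        _write_plain(
            path,
            dose.grid,
            np.round(dose.dose, 3),
            kind="dose",
            prescription=dose.prescription,
        )


# ---------------------------------------------------------------------------
# perirectal maps


def _fmt_mm(v: float) -> str:
    return "NA" if not np.isfinite(v) else f"{v:.1f}"


def write_map_csv(pmap: PerirectalMap, path: str | Path) -> None:
    """5x5 map as CSV with offset headers and NA for missing cells."""
    lines = ["z_offset_mm," + ",".join(f"x{dx:+g}" for dx in pmap.col_offsets_x)]
    for r, dz in enumerate(pmap.row_offsets_z):
        cells = ",".join(_fmt_mm(v) for v in pmap.distances[r])
        lines.append(f"{dz:+g},{cells}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_map_csv(path: str | Path) -> PerirectalMap:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    col_offsets = tuple(float(c.lstrip("x")) for c in df.columns)
    row_offsets = tuple(float(r) for r in df.index)
    return PerirectalMap(
        distances=df.to_numpy(dtype=float),
        row_offsets_z=row_offsets,
        col_offsets_x=col_offsets,
    )


def _nan_to_none(v):
    if v is None:
        return None
    v = float(v)
    return None if not np.isfinite(v) else v


def write_map_json(
    pmap: PerirectalMap, path: str | Path, summary: MapSummary | None = None
) -> None:
    payload = {
        "row_offsets_z_mm": list(pmap.row_offsets_z),
        "col_offsets_x_mm": list(pmap.col_offsets_x),
        "distances_mm": [
            [_nan_to_none(round(v, 1)) if np.isfinite(v) else None for v in row]
            for row in pmap.distances
        ],
    }
    if summary is not None:
        payload["summary"] = {
            "row_means_mm": [_nan_to_none(v) for v in summary.row_means],
            "row_sds_mm": [_nan_to_none(v) for v in summary.row_sds],
            "col_means_mm": [_nan_to_none(v) for v in summary.col_means],
            "col_sds_mm": [_nan_to_none(v) for v in summary.col_sds],
            "overall_mean_mm": _nan_to_none(summary.overall_mean),
            "overall_sd_mm": _nan_to_none(summary.overall_sd),
            "n_cells": summary.n_cells,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# per-patient and cohort outputs


def patient_record_json(rec: PatientRecord) -> dict:
    """JSON-ready dict of one patient's metrics (null for missing)."""
    m = rec.metrics
    return {
        "patient_id": rec.patient_id,
        "placement": {
            "gel_volume_cc": round(m.gel_volume_cc, 3),
            "theta_deg": _nan_to_none(m.theta_deg),
            "norm_theta_vol": round(m.norm_theta_vol, 4),
            "gel_com_mm": list(m.gel_com) if m.gel_com else None,
        },
        "symmetry": {
            "category": rec.symmetry.category.value,
            "per_slice": [
                {
                    "z_offset_mm": s.z_offset_mm,
                    "present": s.present,
                    "lateral_deviation_mm": _nan_to_none(s.lateral_deviation_mm),
                }
                for s in rec.symmetry.per_slice
            ],
        },
        "dvh": {k: round(v, 1) for k, v in rec.dvh_metrics.as_flat_dict().items()},
        "constraints": [
            {
                "name": c.name,
                "limit": c.limit,
                "observed": round(c.observed, 1),
                "passed": c.passed,
            }
            for c in rec.constraint_results
        ],
        "perirectal_map_mm": [
            [_nan_to_none(round(v, 1)) if np.isfinite(v) else None for v in row]
            for row in rec.peri_map.distances
        ],
    }


def write_dvh_csv(dose: DoseGrid, rectum: StructureMask, path: str | Path) -> None:
    """Two-column cumulative DVH export (dose_cGy, volume_cc)."""
    from .dosimetry import cumulative_dvh

    dvh = cumulative_dvh(dose, rectum)
    lines = ["dose_cGy,volume_cc"]
    lines += [
        f"{d:.1f},{v:.3f}"
        for d, v in zip(dvh.dose_axis, dvh.volume_at_or_above)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(report: BatteryReport, out_dir: str | Path) -> None:
    """Write the battery report as CSV grids plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.r2_grid.round(2).to_csv(out / "r2_grid.csv", na_rep="NA")
    report.p_grid.to_csv(out / "p_grid.csv", na_rep="NA")
    report.n_grid.to_csv(out / "n_grid.csv", na_rep="NA")
    report.symmetry_tests.to_csv(out / "symmetry_tests.csv", index=False, na_rep="NA")
    report.toxicity_comparison.to_csv(
        out / "toxicity_comparison.csv", index=False, na_rep="NA"
    )
    summary = {
        "multivariable": (
            dataclasses.asdict(report.multivariable) if report.multivariable else None
        ),
        "notes": report.notes,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) mapping of its field names."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "constraints" in payload:
        payload["constraints"] = tuple(payload["constraints"])
    return RunConfig(**payload)
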