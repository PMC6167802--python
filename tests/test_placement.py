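"""Placement angle, normalized theta*volume score and symmetry rubric."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import perispace as ps
from perispace.placement import SymmetryCategory
from conftest import make_mask, slab_mask


def frame_at(p, r, com=None) -> ps.AnatomicFrame:
    com = com if com is not None else (p[0], p[1] - 10.0, p[2])
    return ps.AnatomicFrame(ctv_com=tuple(com), p_point=tuple(p), r_point=tuple(r))


def free_frame(p, r) -> ps.AnatomicFrame:
    """Frame from arbitrary points, bypassing the anatomical P/R ordering
    check — pure-geometry identities hold for any point configuration."""
    frame = ps.AnatomicFrame.__new__(ps.AnatomicFrame)
    object.__setattr__(frame, "ctv_com", tuple(p))
    object.__setattr__(frame, "p_point", tuple(p))
    object.__setattr__(frame, "r_point", tuple(r))
    return frame


def point_gel(g) -> ps.StructureMask:
    """Single-voxel gel whose COM is exactly the requested point."""
    grid = ps.VolumeGrid(dims=(1, 1, 1), spacing=(1, 1, 1), origin=tuple(g))
    return ps.StructureMask(grid, "hydrogel", np.ones((1, 1, 1), dtype=bool))


class TestTheta:
    @pytest.mark.parametrize(
        "p, r, g, expected",
        [
            # collinear interior point: perfect interposition
            ((0, 0, 0), (0, 10, 0), (0, 4, 0), 180.0),
            # perpendicular construction
            ((0, 0, 0), (0, 10, 0), (5, 5, 0), 90.0),
            # arccos((100-25)/125) by direct vector arithmetic
            ((0, 0, 0), (0, 10, 0), (10, 5, 0), 53.13010235),
        ],
    )
    def test_closed_form_examples(self, p, r, g, expected):
        assert ps.theta(frame_at(p, r), point_gel(g)) == pytest.approx(
            expected, abs=1e-6
        )

    def test_empty_gel_is_undefined(self):
        grid = ps.VolumeGrid(dims=(4, 4, 4), spacing=(1, 1, 1))
        assert ps.theta(frame_at((0, 0, 0), (0, 10, 0)), make_mask(grid, "hydrogel", [])) is None

    def test_degenerate_vertex_raises(self):
        from perispace.placement import DegenerateAngleError

        with pytest.raises(DegenerateAngleError):
            ps.theta(frame_at((0, 0, 0), (0, 10, 0)), point_gel((0, 0, 0)))

    def test_symmetric_in_p_and_r(self):
        p, r, g = (1.0, 2.0, 3.0), (4.0, 9.0, -1.0), (0.0, 5.0, 2.0)
        assert ps.theta(free_frame(p, r), point_gel(g)) == pytest.approx(
            ps.theta(free_frame(r, p), point_gel(g))
        )

    @given(
        seed=st.integers(0, 500),
        tx=st.floats(-30, 30),
        ty=st.floats(-30, 30),
        tz=st.floats(-30, 30),
    )
    def test_rigid_motion_invariance(self, seed, tx, ty, tz):
        rng = np.random.default_rng(seed)
        p, r, g = rng.uniform(-20, 20, size=(3, 3))
        if min(np.linalg.norm(p - g), np.linalg.norm(r - g)) < 0.5:
            return
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        t = np.array([tx, ty, tz])
        base = ps.theta(free_frame(p, r), point_gel(g))
        p2, r2, g2 = rot @ p + t, rot @ r + t, rot @ g + t
        assert ps.theta(free_frame(p2, r2), point_gel(g2)) == pytest.approx(
            base, abs=1e-6
        )

    def test_monotone_decrease_along_pr_bisector(self):
        frame = frame_at((0, 0, 0), (0, 10, 0))
        thetas = [
            ps.theta(frame, point_gel((h, 5.0, 0.0))) for h in (0.5, 2, 5, 10, 20)
        ]
        assert all(a > b for a, b in zip(thetas, thetas[1:]))


class TestNormalizedScore:
    @pytest.mark.parametrize(
        "theta_deg, v, vref, expected",
        [
            (180.0, 12.0, 12.0, 1.0),
            (0.0, 12.0, 12.0, 0.0),
            (70.0, 10.3, 20.6, 0.194444),
            (None, 5.0, 10.0, 0.0),
        ],
    )
    def test_examples(self, theta_deg, v, vref, expected):
        assert ps.normalized_theta_volume(theta_deg, v, vref) == pytest.approx(
            expected, abs=1e-4
        )

    def test_invalid_reference_raises(self):
        with pytest.raises(ValueError):
            ps.normalized_theta_volume(90.0, 10.0, 0.0)

    @given(
        t1=st.floats(0, 180), t2=st.floats(0, 180),
        v1=st.floats(0, 30), v2=st.floats(0, 30),
    )
    def test_monotone_in_each_argument(self, t1, t2, v1, v2):
        lo_t, hi_t = sorted((t1, t2))
        lo_v, hi_v = sorted((v1, v2))
        assert ps.normalized_theta_volume(lo_t, lo_v, 20.0) <= (
            ps.normalized_theta_volume(hi_t, lo_v, 20.0) + 1e-12
        )
        assert ps.normalized_theta_volume(lo_t, lo_v, 20.0) <= (
            ps.normalized_theta_volume(lo_t, hi_v, 20.0) + 1e-12
        )

    def test_scales_inversely_with_reference(self):
        assert ps.normalized_theta_volume(90, 10, 40) == pytest.approx(
            ps.normalized_theta_volume(90, 10, 20) / 2
        )


class TestReferenceVolume:
    def test_maximum_of_cohort(self):
        assert ps.cohort_reference_volume([8.0, 10.3, 19.0]) == 19.0

    def test_single_patient(self):
        assert ps.cohort_reference_volume([12.0]) == 12.0

    def test_override_wins(self):
        assert ps.cohort_reference_volume([8.0, 19.0], override_cc=20.0) == 20.0

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            ps.cohort_reference_volume([])


class TestSymmetryAssessment:
    def _frame(self):
        return ps.AnatomicFrame(
            ctv_com=(30.0, 20.0, 30.0),
            p_point=(30.0, 25.0, 30.0),
            r_point=(30.0, 40.0, 30.0),
        )

    def _grid(self):
        return ps.VolumeGrid(dims=(60, 60, 60), spacing=(1, 1, 1))

    def _gel_blocks(self, blocks):
        """blocks: list of (x_center, z_range) 11x6 slabs posterior to the CTV."""
        vox = np.zeros((60, 60, 60), dtype=bool)
        for x_center, (z0, z1) in blocks:
            vox[x_center - 5 : x_center + 6, 27:33, z0 : z1 + 1] = True
        return ps.StructureMask(self._grid(), "hydrogel", vox)

    def test_symmetric_gel_is_sym1(self):
        gel = self._gel_blocks([(30, (15, 45))])
        out = ps.symmetry_assessment(self._frame(), gel)
        assert out.category is SymmetryCategory.SYM1
        assert all(s.present for s in out.per_slice)
        assert all(s.lateral_deviation_mm < 10 for s in out.per_slice)

    def test_one_slice_deviation_1_to_2cm_is_sym2(self):
        # midgland band shifted 15 mm left; the +-1 cm bands on midline
        gel = self._gel_blocks([(30, (35, 45)), (45, (25, 34)), (30, (15, 24))])
        out = ps.symmetry_assessment(self._frame(), gel)
        assert out.category is SymmetryCategory.SYM2
        devs = {s.z_offset_mm: s.lateral_deviation_mm for s in out.per_slice}
        assert devs[0.0] == pytest.approx(15.0, abs=0.5)
        assert devs[10.0] < 10 and devs[-10.0] < 10

    def test_gross_deviation_is_sym3plus(self):
        gel = self._gel_blocks([(30, (35, 45)), (51, (25, 34)), (30, (15, 24))])
        out = ps.symmetry_assessment(self._frame(), gel)
        assert out.category is SymmetryCategory.SYM3PLUS

    def test_gel_only_at_and_above_midgland_is_missing_inf(self):
        gel = self._gel_blocks([(30, (28, 45))])
        out = ps.symmetry_assessment(self._frame(), gel)
        assert out.category is SymmetryCategory.MISSING_INF

    def test_two_absent_slices_is_multi_missing(self):
        gel = self._gel_blocks([(30, (38, 43))])
        out = ps.symmetry_assessment(self._frame(), gel)
        assert out.category is SymmetryCategory.MULTI_MISSING

    def test_stray_voxels_below_presence_threshold_ignored(self):
        vox = np.zeros((60, 60, 60), dtype=bool)
        vox[25:36, 27:33, 35:46] = True  # superior band only
        vox[30, 30, 20] = True  # one stray voxel on the inferior slice
        vox[30, 30, 30] = True  # and one at midgland
        gel = ps.StructureMask(self._grid(), "hydrogel", vox)
        out = ps.symmetry_assessment(self._frame(), gel)
        assert out.category is SymmetryCategory.MULTI_MISSING

    def test_empty_gel_metrics_score_zero(self):
        gel = ps.StructureMask(self._grid(), "hydrogel", np.zeros((60, 60, 60), bool))
        metrics = ps.compute_placement_metrics(self._frame(), gel, 20.0)
        assert metrics.gel_volume_cc == 0.0
        assert metrics.theta_deg is None
        assert metrics.norm_theta_vol == 0.0
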