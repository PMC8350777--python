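import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corticosim as cs
from corticosim import lesion, toycortex
from tests.conftest import SMALL_ROI, SMALL_SPEC, small_grid


class TestContractionAlgebra:
    @pytest.mark.parametrize(
        "r_vol, r_lin",
        # 1 - (1-r)^(1/3); note 5% volume is 1.695% per axis (often quoted
        # rounded as ~1.7%), the others land on 7.17/11.21/15.66%
        [(0.05, 0.016952), (0.20, 0.0717), (0.30, 0.1121), (0.40, 0.1566)],
    )
    def test_volume_to_linear_table(self, r_vol, r_lin):
        assert cs.linear_from_volume_contraction(r_vol) == pytest.approx(r_lin, abs=5e-5)

    def test_identity_and_analytic_case(self):
        assert cs.linear_from_volume_contraction(0.0) == 0.0
        # (1 - 0.2)^3 = 0.512, so 48.8% volume loss is a 20% linear loss
        assert cs.linear_from_volume_contraction(0.488) == pytest.approx(0.200, abs=1e-12)

    @given(st.floats(min_value=-0.5, max_value=0.9))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_round_trip(self, r):
        back = cs.volume_from_linear_contraction(cs.linear_from_volume_contraction(r))
        assert back == pytest.approx(r, abs=1e-12)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            cs.linear_from_volume_contraction(1.0)

    def test_detectable_change_arithmetic(self):
        assert cs.detectable_change_mm(0.07, 5.0) == pytest.approx(0.35)
        assert cs.detectable_change_mm(0.1121, 10.0) == pytest.approx(1.12, abs=5e-3)


class TestRoiMasks:
    def test_cube_voxel_counts(self):
        grid = small_grid(40)
        for size, expect in ((10.0, 1000), (2.0, 8)):
            roi = cs.ROISpec(corner_world=(-5.0, -5.0, -5.0), size_mm=size)
            assert cs.make_roi_mask(roi, grid).data.sum() == expect

    def test_ellipsoid_matches_brute_force(self):
        grid = small_grid(40)
        roi = cs.ROISpec(corner_world=(-5.0, -5.0, -5.0), size_mm=10.0, shape="ellipsoid")
        mask = cs.make_roi_mask(roi, grid)
        center = np.array([0.0, 0.0, 0.0])
        radii = np.array([5.0, 5.0, 5.0])
        count = 0
        for i in range(40):
            for j in range(40):
                for k in range(40):
                    p = grid.voxel_to_world(np.array([i, j, k], float))
                    if np.sum(((p - center) / radii) ** 2) <= 1.0:
                        count += 1
        assert mask.data.sum() == count

    def test_center_is_corner_plus_half_size(self):
        roi = cs.ROISpec(corner_world=(2.0, -4.0, 6.0), size_mm=10.0)
        np.testing.assert_allclose(roi.center_world, (7.0, 1.0, 11.0))

    def test_box_outside_grid_rejected(self):
        grid = small_grid(20)
        roi = cs.ROISpec(corner_world=(5.0, 5.0, 5.0), size_mm=10.0)
        with pytest.raises(ValueError, match="outside the grid"):
            cs.make_roi_mask(roi, grid)


class TestToleranceMask:
    def test_single_voxel_ring_is_26_neighbourhood(self):
        grid = small_grid(11)
        mask = grid.like(np.zeros((11, 11, 11), dtype=bool))
        mask.data[5, 5, 5] = True
        ring = cs.make_tolerance_mask(mask, 1.0, grid)
        assert ring.data.sum() == 26
        assert not ring.data[5, 5, 5]

    def test_zero_pad_rejected(self):
        grid = small_grid(11)
        mask = grid.like(np.zeros((11, 11, 11), dtype=bool))
        mask.data[5, 5, 5] = True
        with pytest.raises(ValueError, match="at least one voxel"):
            cs.make_tolerance_mask(mask, 0.0, grid)

    def test_ring_disjoint_and_union_contiguous(self):
        from scipy import ndimage

        grid = small_grid(30)
        roi = cs.ROISpec(corner_world=(-3.0, -3.0, -3.0), size_mm=6.0)
        mask = cs.make_roi_mask(roi, grid)
        ring = cs.make_tolerance_mask(mask, 3.0, grid)
        assert not np.any(np.asarray(mask.data, bool) & np.asarray(ring.data, bool))
        union = np.asarray(mask.data, bool) | np.asarray(ring.data, bool)
        _, n_components = ndimage.label(union)
        assert n_components == 1

    def test_ring_reaching_border_rejected(self):
        grid = small_grid(12)
        roi = cs.ROISpec(corner_world=(-3.0, -3.0, -3.0), size_mm=6.0)
        mask = cs.make_roi_mask(roi, grid)
        with pytest.raises(ValueError, match="border"):
            cs.make_tolerance_mask(mask, 4.0, grid)


class TestDeterminantMap:
    @pytest.mark.parametrize("contraction, value", [(0.40, 0.60), (0.0, 1.0), (-0.10, 1.10)])
    def test_values(self, contraction, value):
        grid = small_grid(20)
        roi = cs.ROISpec(corner_world=(-3.0, -3.0, -3.0), size_mm=6.0)
        mask = cs.make_roi_mask(roi, grid)
        det = cs.make_determinant_map(mask, contraction, grid)
        inside = np.asarray(mask.data, bool)
        assert np.all(det.data[inside] == value)
        assert np.all(det.data[~inside] == 1.0)


class TestJacobianDeterminant:
    def test_identity_field(self):
        grid = small_grid(12)
        u = np.zeros((3, 12, 12, 12))
        jd = cs.jacobian_determinant(u, grid)
        np.testing.assert_allclose(jd.data, 1.0, atol=1e-12)

    def test_uniform_scaling_is_cubed_factor(self):
        grid = small_grid(16)
        xyz = grid.voxel_center_grid()
        u = 0.1 * np.moveaxis(xyz - xyz.mean(axis=(0, 1, 2)), -1, 0)
        jd = cs.jacobian_determinant(u, grid)
        np.testing.assert_allclose(jd.data, 1.1**3, atol=1e-9)

    def test_polynomial_field_matches_dense_oracle(self):
        # quadratic displacement: the analytic Jacobian is exact, the
        # central-difference one should agree to high order on a fine grid
        n = 16
        grid = small_grid(n, spacing=0.5)
        xyz = grid.voxel_center_grid()
        x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
        a, b, c = 0.004, 0.003, 0.002
        u = np.stack([a * x**2, b * y**2 + 0.001 * x, c * z**2], axis=0)
        jd = cs.jacobian_determinant(u, grid)
        # closed-form gradient of the quadratic map
        gxx, gyy, gzz = 1 + 2 * a * x, 1 + 2 * b * y, 1 + 2 * c * z
        expected = gxx * gyy * gzz  # off-diagonal terms: only dy/dx = 0.001 -> no det effect
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(jd.data[interior], expected[interior], atol=1e-6)


class TestSolver:
    def test_unit_target_returns_zero_field(self):
        grid = small_grid(16)
        free = grid.like(np.ones((16, 16, 16), dtype=bool))
        det = grid.like(np.ones((16, 16, 16)))
        fld = cs.solve_deformation_field(det, free)
        assert not np.any(fld.displacement)
        assert fld.solver_log == [0.0]

    def test_contract_small_roi(self, noiseless_phantom, solved_field):
        fld = solved_field["field"]
        roi_b = np.asarray(solved_field["roi_mask"].data, bool)
        free_b = np.asarray(solved_field["free"].data, bool)
        jd = cs.jacobian_determinant(fld)
        assert jd.data[roi_b].mean() == pytest.approx(0.8, abs=0.02)
        assert jd.data.min() > 0
        assert np.abs(fld.displacement[:, ~free_b]).max() == 0.0

    def test_error_log_monotone_non_increasing(self, solved_field):
        log = np.asarray(solved_field["field"].solver_log)
        assert np.all(np.diff(log) <= 1e-9)

    def test_free_mask_must_cover_target(self):
        grid = small_grid(16)
        det = grid.like(np.ones((16, 16, 16)))
        det.data[8, 8, 8] = 0.8
        free = grid.like(np.zeros((16, 16, 16), dtype=bool))
        with pytest.raises(ValueError, match="free_mask"):
            cs.solve_deformation_field(det, free)

    def test_nonpositive_target_rejected(self):
        grid = small_grid(16)
        det = grid.like(np.ones((16, 16, 16)))
        det.data[8, 8, 8] = -0.5
        free = grid.like(np.ones((16, 16, 16), dtype=bool))
        with pytest.raises(ValueError, match="positive"):
            cs.solve_deformation_field(det, free)


class TestApplyDeformation:
    def test_zero_field_is_identity(self, noiseless_phantom):
        grid = noiseless_phantom.volume
        free = grid.like(np.ones(grid.shape, dtype=bool))
        fld = cs.DeformationField(np.zeros((3,) + grid.shape), grid, free)
        out = cs.apply_deformation(grid, fld)
        np.testing.assert_array_equal(out.data, grid.data)

    def test_uniform_integer_translation_shifts_array(self):
        rng = np.random.default_rng(3)
        grid = small_grid(12)
        grid.data[:] = rng.normal(size=(12, 12, 12))
        free = grid.like(np.ones((12, 12, 12), dtype=bool))
        u = np.zeros((3, 12, 12, 12))
        u[0] = 2.0  # +2 voxels along axis 0: content moves forward by 2
        fld = cs.DeformationField(u, grid, free)
        out = cs.apply_deformation(grid, fld)
        np.testing.assert_allclose(out.data[2:, :, :], grid.data[:-2, :, :], atol=1e-12)

    def test_grid_mismatch_rejected(self, noiseless_phantom, solved_field):
        other = small_grid(16)
        with pytest.raises(ValueError, match="different grids"):
            cs.apply_deformation(other, solved_field["field"])

    def test_gm_mass_in_roi_decreases(self, noiseless_phantom, solved_field):
        deformed = cs.apply_deformation(noiseless_phantom.volume, solved_field["field"])
        means = dict(zip(("csf", "gm", "wm"), SMALL_SPEC.intensity_means))
        cls = toycortex.classify_tissues(deformed, means)
        roi_b = solved_field["roi_mask"]
        before = toycortex.tissue_fractions(noiseless_phantom.class_maps, roi_b)["gm"]
        after = toycortex.tissue_fractions(cls.class_maps, roi_b)["gm"]
        assert after < before


class TestLocality:
    def test_outside_free_region_unchanged_exactly(self, noiseless_phantom, solved_field):
        deformed = cs.apply_deformation(noiseless_phantom.volume, solved_field["field"])
        max_abs, _ = cs.verify_locality(
            noiseless_phantom.volume, deformed, solved_field["free"]
        )
        assert max_abs == 0.0

    def test_identity_deformation_changes_nothing(self, noiseless_phantom):
        grid = noiseless_phantom.volume
        free = grid.like(np.ones(grid.shape, dtype=bool))
        fld = cs.DeformationField(np.zeros((3,) + grid.shape), grid, free)
        deformed = cs.apply_deformation(grid, fld)
        max_abs, _ = cs.verify_locality(grid, deformed, free)
        assert max_abs == 0.0

    def test_class_change_outside_roi_below_bound(self, noiseless_phantom, solved_field):
        deformed = cs.apply_deformation(noiseless_phantom.volume, solved_field["field"])
        means = dict(zip(("csf", "gm", "wm"), SMALL_SPEC.intensity_means))
        before = toycortex.classify_tissues(noiseless_phantom.volume, means).class_maps
        after = toycortex.classify_tissues(deformed, means).class_maps
        _, table = cs.verify_locality(
            noiseless_phantom.volume, deformed, solved_field["free"],
            class_maps_original=before, class_maps_deformed=after,
            roi_mask=solved_field["roi_mask"],
        )
        assert table["outside_pp"].abs().max() <= 0.2
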