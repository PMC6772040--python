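"""Displacement-field algebra: Jacobians, composition, inversion, warping."""

import numpy as np
import pytest

import volref as vr
from volref.fields import interior_mask

ANISO = (2.07, 2.07, 8.0)


class TestJacobianDeterminant:
    def test_translation_is_volume_preserving(self, small_grid):
        f = vr.DisplacementField.constant(small_grid, (5.0, -3.0, 2.0))
        jac = vr.jacobian_determinant(f)
        assert np.all(jac.data == pytest.approx(1.0))

    def test_uniaxial_stretch_doubles_volume(self, small_grid):
        pts = small_grid.meshgrid()
        u = np.zeros(tuple(small_grid.shape) + (3,))
        u[..., 0] = pts[..., 0]  # f(x) = (2 x1, x2, x3)
        jac = vr.jacobian_determinant(vr.DisplacementField(u, small_grid))
        interior = jac.data[1:-1, 1:-1, 1:-1]
        assert interior == pytest.approx(2.0, abs=1e-10)

    def test_affine_field_matches_det(self, small_grid):
        rng = np.random.default_rng(7)
        a = 0.1 * rng.normal(size=(3, 3))
        pts = small_grid.meshgrid()
        u = np.einsum("ij,...j->...i", a, pts)
        jac = vr.jacobian_determinant(vr.DisplacementField(u, small_grid))
        expected = np.linalg.det(np.eye(3) + a)
        assert jac.data[1:-1, 1:-1, 1:-1] == pytest.approx(expected, abs=1e-10)

    def test_matches_per_voxel_determinant_oracle(self, smooth_field):
        """Vectorized determinant equals an explicit per-voxel 3x3 expansion."""
        jac = vr.jacobian_determinant(smooth_field)
        sp = smooth_field.spacing
        grads = [
            np.gradient(smooth_field.data[..., i], sp[0], sp[1], sp[2])
            for i in range(3)
        ]
        idx = [(3, 4, 5), (8, 2, 13), (1, 14, 7), (10, 10, 10)]
        for v in idx:
            m = np.eye(3)
            for i in range(3):
                for j in range(3):
                    m[i, j] += grads[i][j][v]
            assert jac.data[v] == pytest.approx(np.linalg.det(m), abs=1e-12)

    def test_degenerate_grid_rejected(self):
        g = vr.GridInfo((1, 8, 8), ANISO)
        with pytest.raises(ValueError):
            vr.jacobian_determinant(vr.DisplacementField.zeros(g))


class TestCompose:
    def test_translations_add(self, small_grid):
        t1 = vr.DisplacementField.constant(small_grid, (1.0, 2.0, -3.0))
        t2 = vr.DisplacementField.constant(small_grid, (0.5, -1.0, 4.0))
        comp = vr.compose(t1, t2)
        np.testing.assert_allclose(comp.data, t1.data + t2.data, atol=1e-12)

    def test_zero_inner_is_identity(self, smooth_field):
        zero = vr.DisplacementField.zeros(smooth_field.grid)
        comp = vr.compose(smooth_field, zero)
        np.testing.assert_allclose(comp.data, smooth_field.data, atol=1e-12)

    def test_compose_with_inverse_is_near_identity(self, smooth_field):
        inv = vr.invert(smooth_field, tol=0.01, max_iter=200)
        rt = vr.compose(smooth_field, inv)
        interior = interior_mask(smooth_field.grid, 2)
        vox = np.abs(rt.data) / smooth_field.spacing
        assert np.max(np.linalg.norm(vox, axis=-1)[interior]) <= 0.1

    def test_associative_on_translations(self, small_grid):
        a = vr.DisplacementField.constant(small_grid, (1.0, 0.0, 2.0))
        b = vr.DisplacementField.constant(small_grid, (0.0, -1.0, 0.5))
        c = vr.DisplacementField.constant(small_grid, (2.0, 2.0, -2.0))
        left = vr.compose(vr.compose(a, b), c)
        right = vr.compose(a, vr.compose(b, c))
        np.testing.assert_allclose(left.data, right.data, atol=1e-12)


class TestInvert:
    def test_zero_field(self, small_grid):
        inv = vr.invert(vr.DisplacementField.zeros(small_grid))
        assert np.all(inv.data == 0)

    def test_translation_inverse_is_negation(self, small_grid):
        t = vr.DisplacementField.constant(small_grid, (3.0, -2.0, 5.0))
        inv = vr.invert(t, tol=1e-6, max_iter=100)
        np.testing.assert_allclose(inv.data, -t.data, atol=1e-6)

    def test_roundtrip_residual_bound(self, smooth_field):
        inv = vr.invert(smooth_field, tol=0.01, max_iter=200)
        rt = vr.compose(smooth_field, inv)
        interior = interior_mask(smooth_field.grid, 2)
        assert rt.magnitude()[interior].max() < 0.5

    def test_roundtrip_improves_with_tolerance(self, smooth_field):
        interior = interior_mask(smooth_field.grid, 2)
        residuals = []
        for tol in (1.0, 0.1, 0.001):
            inv = vr.invert(smooth_field, tol=tol, max_iter=500)
            rt = vr.compose(smooth_field, inv)
            residuals.append(rt.magnitude()[interior].max())
        assert residuals[2] <= residuals[0] + 1e-12
        assert residuals[2] <= residuals[1] + 1e-12

    def test_nonconvergence_warns_but_returns(self, small_grid):
        big = vr.make_diffeomorphism(
            (16, 16, 16), ANISO, magnitude_mm=10.0, min_jacobian=0.05, seed=3
        )
        with pytest.warns(RuntimeWarning):
            inv, report = vr.invert(big, tol=1e-9, max_iter=2, full_output=True)
        assert not report.converged
        assert inv.data.shape == big.data.shape


class TestWarp:
    def test_zero_field_identity(self, phantom48):
        image, _ = phantom48
        zero = vr.DisplacementField.zeros(image.grid)
        out = vr.warp(image, zero, interp="linear")
        np.testing.assert_allclose(out.data, image.data, atol=1e-12)

    def test_impulse_shifts_by_one_voxel(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[8, 8, 8] = 1.0
        img = vr.ImageVolume(data[None], small_grid)
        t = vr.DisplacementField.constant(small_grid, (0.0, small_grid.spacing[1], 0.0))
        out = vr.warp(img, t, interp="linear")
        assert out.data[0][8, 7, 8] == pytest.approx(1.0)
        assert out.data[0][8, 8, 8] == pytest.approx(0.0)

    def test_nearest_invents_no_labels(self, small_grid, smooth_field):
        rng = np.random.default_rng(0)
        lab = vr.LabelVolume(rng.integers(0, 4, small_grid.shape), small_grid)
        out = vr.warp(lab, smooth_field, interp="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))

    def test_linear_on_labels_rejected(self, small_grid):
        lab = vr.LabelVolume(np.zeros(small_grid.shape, dtype=int), small_grid)
        with pytest.raises(ValueError):
            vr.warp(lab, vr.DisplacementField.zeros(small_grid), interp="linear")

    def test_zero_field_preserves_label_counts(self, small_grid):
        rng = np.random.default_rng(1)
        lab = vr.LabelVolume(rng.integers(0, 5, small_grid.shape), small_grid)
        out = vr.warp(lab, vr.DisplacementField.zeros(small_grid), interp="nearest")
        for l in range(5):
            assert (out.data == l).sum() == (lab.data == l).sum()


class TestHalfvoxelResample:
    def test_constant_image_unchanged_interior(self, small_grid):
        img = vr.ImageVolume(np.full(small_grid.shape, 7.0)[None], small_grid)
        out = vr.halfvoxel_resample(img)
        assert out.data[0][:-1, :-1, :-1] == pytest.approx(7.0)

    def test_step_edge_midpoint(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[8:, :, :] = 1.0
        img = vr.ImageVolume(data[None], small_grid)
        out = vr.halfvoxel_resample(img)
        assert out.data[0][7, 4, 4] == pytest.approx(0.5)

    def test_twice_versus_full_voxel_shift_bounded(self, phantom48):
        image, _ = phantom48
        twice = vr.halfvoxel_resample(vr.halfvoxel_resample(image))
        full = vr.warp(
            image,
            vr.DisplacementField.constant(image.grid, image.spacing),
            interp="linear",
        )
        diff = np.abs(twice.data - full.data)[:, :-2, :-2, :-2]
        local_range = image.data.max() - image.data.min()
        assert diff.max() <= local_range
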