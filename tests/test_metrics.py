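"""Evaluation metrics: V transform, AAVC, AICE, MSE, MI, Dice, voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import volref as vr

ANISO = (2.07, 2.07, 8.0)


@pytest.fixture(scope="module")
def grid():
    return vr.GridInfo((16, 16, 16), ANISO)


@pytest.fixture(scope="module")
def full_roi(grid):
    return vr.MaskVolume(np.ones(grid.shape, dtype=bool), grid)


class TestVTransform:
    @pytest.mark.parametrize(
        "j,expected",
        [(1.0, 0.0), (2.0, 1.0), (0.5, -1.0), (0.25, -3.0)],
    )
    def test_branch_values(self, j, expected):
        assert vr.v_transform(np.array([j]))[0] == pytest.approx(expected)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_under_inversion(self, j):
        v1 = vr.v_transform(np.array([j]))[0]
        v2 = vr.v_transform(np.array([1.0 / j]))[0]
        assert abs(v1) == pytest.approx(abs(v2), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            vr.v_transform(np.array([0.0]))


class TestAAVC:
    def test_identity_is_zero(self, grid, full_roi):
        assert vr.aavc(vr.DisplacementField.zeros(grid), full_roi) == 0.0

    def test_uniform_doubling_gives_one(self, grid):
        # f = (2 x1, x2, x3) has J = 2 at interior voxels
        pts = grid.meshgrid()
        u = np.zeros(tuple(grid.shape) + (3,))
        u[..., 0] = pts[..., 0]
        roi = vr.MaskVolume(
            np.pad(np.ones((14, 14, 14), bool), 1, constant_values=False), grid
        )
        assert vr.aavc(vr.DisplacementField(u, grid), roi) == pytest.approx(1.0)

    def test_mixed_compression_expansion(self, grid, full_roi):
        # |V(2)| = |V(0.5)| = 1, so the ROI mean of |V| over {2, 0.5} is 1
        v = np.abs(vr.v_transform(np.array([2.0, 0.5])))
        assert v.mean() == pytest.approx(1.0)

    def test_nonnegative(self, smooth_field):
        roi = vr.MaskVolume(np.ones(smooth_field.grid.shape, bool), smooth_field.grid)
        assert vr.aavc(smooth_field, roi) >= 0.0


class TestRobustAAVC:
    def test_uniform_distribution_equals_plain(self, grid, full_roi):
        t = vr.DisplacementField.constant(grid, (1.0, 2.0, 3.0))
        assert vr.robust_aavc(t, full_roi) == vr.aavc(t, full_roi)

    def test_outlier_excluded(self):
        # direct check of the exclusion rule on a synthetic |V| sample
        v = np.concatenate([np.full(99, 0.1), [50.0]])
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        keep = np.abs(v - med) <= 2.5 * mad
        assert keep.sum() == 99
        assert v[keep].mean() == pytest.approx(0.1)

    def test_large_k_equals_plain(self, smooth_field):
        roi = vr.MaskVolume(np.ones(smooth_field.grid.shape, bool), smooth_field.grid)
        assert vr.robust_aavc(smooth_field, roi, k=1e12) == pytest.approx(
            vr.aavc(smooth_field, roi)
        )


class TestAICE:
    def test_exact_inverse_pair_small(self, smooth_field, full_roi):
        inv = vr.invert(smooth_field, tol=0.01, max_iter=300)
        interior = np.zeros(smooth_field.grid.shape, bool)
        interior[2:-2, 2:-2, 2:-2] = True
        roi = vr.MaskVolume(interior, smooth_field.grid)
        # (f o f^-1)(x) - x: bounded by the fixed-point tolerance
        assert vr.aice(inv, smooth_field, roi) <= 0.1

    def test_doubled_translation(self, grid, full_roi):
        t = vr.DisplacementField.constant(grid, (3.0, 0.0, 4.0))
        assert vr.aice(t, t, full_roi) == pytest.approx(10.0)  # 2 * ||t||

    def test_translation_and_negation_cancel(self, grid, full_roi):
        t = vr.DisplacementField.constant(grid, (3.0, -1.0, 4.0))
        assert vr.aice(t, -t, full_roi) == pytest.approx(0.0, abs=1e-12)


class TestMSE:
    def test_identical_zero(self, grid, full_roi):
        img = vr.ImageVolume(np.random.default_rng(0).normal(size=grid.shape)[None], grid)
        assert vr.mse(img, img, full_roi) == 0.0

    def test_constant_offset(self, grid, full_roi):
        a = vr.ImageVolume(np.zeros(grid.shape)[None], grid)
        b = vr.ImageVolume(np.full(grid.shape, 3.0)[None], grid)
        assert vr.mse(a, b, full_roi) == pytest.approx(9.0)

    def test_matches_elementwise_oracle(self, grid, full_roi):
        rng = np.random.default_rng(1)
        a = vr.ImageVolume(rng.normal(size=grid.shape)[None], grid)
        b = vr.ImageVolume(rng.normal(size=grid.shape)[None], grid)
        acc = 0.0
        for v in np.ndindex(grid.shape):
            acc += (a.data[0][v] - b.data[0][v]) ** 2
        assert vr.mse(a, b, full_roi) == pytest.approx(acc / np.prod(grid.shape), abs=1e-12)


class TestMutualInformation:
    def test_self_information_equals_entropy(self, grid, full_roi):
        rng = np.random.default_rng(2)
        img = vr.ImageVolume(rng.normal(size=grid.shape)[None], grid)
        mi = vr.mutual_information(img, img, full_roi)
        hist, _ = np.histogram(img.data[0].ravel(), bins=256)
        p = hist / hist.sum()
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(h, rel=1e-9)

    def test_independent_noise_near_zero(self):
        # histogram MI has finite-sample bias ~ (B-1)^2 / 2N nats; at
        # N ~ 1e5 the bound 0.05 requires B << 100, so independence is
        # checked at 32 bins where the bias is ~0.005
        g = vr.GridInfo((47, 47, 47), ANISO)
        roi = vr.MaskVolume(np.ones(g.shape, bool), g)
        rng = np.random.default_rng(3)
        a = vr.ImageVolume(rng.normal(size=g.shape)[None], g)
        b = vr.ImageVolume(rng.normal(size=g.shape)[None], g)
        assert vr.mutual_information(a, b, roi, bins=32) < 0.05

    def test_bijective_remap_preserves_mi(self, grid, full_roi):
        rng = np.random.default_rng(4)
        data = rng.integers(0, 256, grid.shape).astype(float)
        a = vr.ImageVolume(data[None], grid)
        b = vr.ImageVolume((255.0 - data)[None], grid)  # bin-aligned inversion
        mi_ab = vr.mutual_information(a, b, full_roi)
        mi_aa = vr.mutual_information(a, a, full_roi)
        assert mi_ab == pytest.approx(mi_aa, rel=1e-9)

    def test_constant_image_zero(self, grid, full_roi):
        c = vr.ImageVolume(np.full(grid.shape, 5.0)[None], grid)
        assert vr.mutual_information(c, c, full_roi) == pytest.approx(0.0)


class TestDice:
    def _lab(self, data, grid):
        return vr.LabelVolume(data.astype(int), grid)

    def test_identical_masks(self, grid):
        rng = np.random.default_rng(5)
        lab = self._lab(rng.integers(0, 3, grid.shape), grid)
        assert vr.dice(lab, lab, 1) == 1.0
        assert vr.dice(lab, lab, 2) == 1.0

    def test_disjoint_masks(self, grid):
        a = np.zeros(grid.shape)
        b = np.zeros(grid.shape)
        a[:4], b[8:] = 1, 1
        assert vr.dice(self._lab(a, grid), self._lab(b, grid), 1) == 0.0

    def test_half_overlap(self, grid):
        a = np.zeros(grid.shape)
        b = np.zeros(grid.shape)
        a.flat[:100] = 1
        b.flat[50:150] = 1
        assert vr.dice(self._lab(a, grid), self._lab(b, grid), 1) == pytest.approx(0.5)

    def test_symmetric(self, grid):
        rng = np.random.default_rng(6)
        a = self._lab(rng.integers(0, 3, grid.shape), grid)
        b = self._lab(rng.integers(0, 3, grid.shape), grid)
        assert vr.dice(a, b, 1) == vr.dice(b, a, 1)

    def test_absent_label_defined_as_one(self, grid):
        z = self._lab(np.zeros(grid.shape), grid)
        assert vr.dice(z, z, 7) == 1.0


class TestMajorityVote:
    def _lab(self, value_at, grid, base=0):
        data = np.full(grid.shape, base, dtype=int)
        for (v, lab) in value_at:
            data[v] = lab
        return vr.LabelVolume(data, grid)

    def test_strict_majority_wins(self, grid):
        vols = [
            self._lab([((2, 2, 2), 5)], grid),
            self._lab([((2, 2, 2), 5)], grid),
            self._lab([((2, 2, 2), 3)], grid),
        ]
        fused = vr.majority_vote(vols)
        assert fused.data[2, 2, 2] == 5

    def test_no_majority_falls_back_to_background(self, grid):
        vols = [
            self._lab([((2, 2, 2), 5)], grid),
            self._lab([((2, 2, 2), 3)], grid),
            self._lab([((2, 2, 2), 0)], grid),
        ]
        fused = vr.majority_vote(vols)
        assert fused.data[2, 2, 2] == 0

    def test_single_input_unchanged(self, grid):
        rng = np.random.default_rng(7)
        lab = vr.LabelVolume(rng.integers(0, 4, grid.shape), grid)
        fused = vr.majority_vote([lab])
        np.testing.assert_array_equal(fused.data, lab.data)

    def test_permutation_invariant(self, grid):
        rng = np.random.default_rng(8)
        vols = [
            vr.LabelVolume(rng.integers(0, 4, grid.shape), grid) for _ in range(5)
        ]
        a = vr.majority_vote(vols)
        b = vr.majority_vote(vols[::-1])
        np.testing.assert_array_equal(a.data, b.data)
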