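import numpy as np
import pytest

from aoslo.elastic import (
    BSplineDeformation,
    ElasticOpts,
    EnergyWeights,
    bspline3,
    composition_residual,
    deform_image,
    register_elastic_pair,
    stabilize_elastic,
)
from aoslo.rigid import FrameStack

# Compact settings keep each pair registration around a second on
# 96-px frames without hurting recovery accuracy at these amplitudes.
FAST_OPTS = ElasticOpts(schedule=((4, 4), (2, 6), (1, 10)), max_iter=40)


def random_deformation(rng, intervals, shape, sd):
    gy, gx = intervals
    return BSplineDeformation(
        gy + 3, gx + 3,
        rng.normal(0, sd, (gy + 3, gx + 3)),
        rng.normal(0, sd, (gy + 3, gx + 3)),
        shape[0], shape[1],
    )


class TestBSplineBasics:
    def test_partition_of_unity(self):
        t = np.linspace(-0.49, 0.49, 21)
        total = sum(bspline3(t - k) for k in range(-2, 3))
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_zero_coefficients_identity(self, small_phantom):
        d = BSplineDeformation.identity((4, 4), small_phantom.shape)
        out, mask = deform_image(small_phantom, d)
        np.testing.assert_allclose(out, small_phantom, atol=1e-9)
        assert mask.all()

    def test_constant_image_unchanged_on_valid_pixels(self, rng):
        img = np.full((64, 64), 77.0)
        d = random_deformation(rng, (4, 4), img.shape, 3.0)
        out, mask = deform_image(img, d)
        np.testing.assert_allclose(out[mask], 77.0, atol=1e-9)

    def test_uniform_coefficients_are_uniform_shift(self, small_phantom):
        # partition of unity: equal coefficients sum to a constant shift
        g = 5
        cy = np.zeros((g + 3, g + 3))
        cx = np.full((g + 3, g + 3), 2.0)
        d = BSplineDeformation(g + 3, g + 3, cy, cx, *small_phantom.shape)
        dy, dx = d.dense_field()
        np.testing.assert_allclose(dy, 0.0, atol=1e-10)
        np.testing.assert_allclose(dx, 2.0, atol=1e-10)
        out, mask = deform_image(small_phantom, d)
        shifted = small_phantom[:, 2:]  # out(p) = in(p + 2 along x)
        np.testing.assert_allclose(out[:, :-2][mask[:, :-2]],
                                   shifted[mask[:, :-2]], atol=1e-6)

    def test_coefficient_shape_validated(self):
        with pytest.raises(ValueError):
            BSplineDeformation(7, 7, np.zeros((7, 6)), np.zeros((7, 7)), 64, 64)


class TestPairRegistration:
    def test_self_registration_near_identity(self, small_phantom):
        fw, bw, _ = register_elastic_pair(small_phantom, small_phantom, opts=FAST_OPTS)
        assert fw.mean_abs_displacement() < 0.1
        assert bw.mean_abs_displacement() < 0.1

    def test_known_warp_recovery(self, cone_phantom, rng):
        true = random_deformation(rng, (6, 6), cone_phantom.shape, 3.0)
        src, _ = deform_image(cone_phantom, true)
        fw, _, _ = register_elastic_pair(src, cone_phantom)
        dy, dx = true.dense_field()
        res = composition_residual(fw, dy, dx, border=8)
        assert res.mean() < 0.5

    def test_energy_trace_non_increasing_within_levels(self, small_phantom, rng):
        true = random_deformation(rng, (4, 4), small_phantom.shape, 2.0)
        src, _ = deform_image(small_phantom, true)
        _, _, trace = register_elastic_pair(src, small_phantom, opts=FAST_OPTS)
        assert len(trace) == len(FAST_OPTS.effective_schedule(small_phantom.shape))
        for level_trace in trace:
            assert len(level_trace) >= 2
            assert np.all(np.diff(level_trace) <= 1e-15)

    def test_inverse_consistency_tightens_with_weight(self, small_phantom, rng):
        true = random_deformation(rng, (4, 4), small_phantom.shape, 2.5)
        src, _ = deform_image(small_phantom, true)
        residuals = []
        H, W = small_phantom.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        for w_c in (0.0, 0.3, 3.0):
            fw, bw, _ = register_elastic_pair(
                src, small_phantom, EnergyWeights(1.0, w_c, 0.1), FAST_OPTS
            )
            dby, dbx = bw.dense_field()
            fy, fx = fw.displacement_at(yy + dby, xx + dbx)
            ic = np.hypot(dby + fy, dbx + fx)[8:-8, 8:-8]
            residuals.append(ic.mean())
        assert residuals[2] < 0.5
        # monotone in the weight up to sub-millipixel saturation once
        # both residuals are far below the 0.5 px requirement
        assert residuals[1] <= residuals[0] + 1e-6
        assert residuals[2] <= residuals[0] + 1e-6
        assert residuals[2] <= residuals[1] + 2e-3

    def test_intensity_rescaled_pair_gives_same_deformation(self, small_phantom, rng):
        # MSE similarity is scale-covariant when both images scale together
        true = random_deformation(rng, (4, 4), small_phantom.shape, 2.0)
        src, _ = deform_image(small_phantom, true)
        fw1, _, _ = register_elastic_pair(src, small_phantom, opts=FAST_OPTS)
        fw2, _, _ = register_elastic_pair(0.5 * src, 0.5 * small_phantom, opts=FAST_OPTS)
        d1y, d1x = fw1.dense_field()
        d2y, d2x = fw2.dense_field()
        diff = np.hypot(d1y - d2y, d1x - d2x)[8:-8, 8:-8]
        assert diff.mean() < 0.2

    def test_mismatched_shapes_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            register_elastic_pair(small_phantom, small_phantom[:-2, :])


class TestStackStabilization:
    def test_two_frames_one_registration(self, small_phantom, rng):
        true = random_deformation(rng, (4, 4), small_phantom.shape, 2.0)
        warped, _ = deform_image(small_phantom, true)
        stack = FrameStack(np.stack([small_phantom, warped]))
        out, deformations = stabilize_elastic(stack, opts=FAST_OPTS)
        assert len(deformations) == 1
        np.testing.assert_array_equal(out.frames[0], small_phantom)

    def test_motion_free_noisy_stack_no_hallucinated_warps(self, small_phantom, rng):
        frames = np.stack([
            np.clip(small_phantom + rng.normal(0, 3, small_phantom.shape), 0, 255)
            for _ in range(3)
        ])
        _, deformations = stabilize_elastic(FrameStack(frames), opts=FAST_OPTS)
        mean_d = np.mean([d.mean_abs_displacement() for d in deformations])
        assert mean_d < 0.3

    def test_residual_shrinks_versus_rigid_only(self, cone_phantom, rng):
        # post-elastic dense residual must beat the rigid-only residual
        true = random_deformation(rng, (6, 6), cone_phantom.shape, 3.0)
        src, _ = deform_image(cone_phantom, true)
        dy, dx = true.dense_field()
        rigid_only = np.hypot(dy, dx)[8:-8, 8:-8].mean()  # uncorrected
        fw, _, _ = register_elastic_pair(src, cone_phantom)
        res = composition_residual(fw, dy, dx, border=8).mean()
        assert res < 0.5
        assert res < rigid_only
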