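import numpy as np
import pytest
from scipy import ndimage

from aoslo.rigid import (
    FrameStack,
    RigidOpts,
    RigidTransform,
    apply_rigid,
    largest_interior_rectangle,
    register_rigid_pair,
    stabilize_and_crop,
    transform_rms_difference,
)
from aoslo.synthetic import generate_scene, render_video
from tests.conftest import small_scene_config, still_motion


def warp_with(transform: RigidTransform, reference: np.ndarray) -> np.ndarray:
    """Generate a source frame carrying `transform` as ground truth:
    frame(p) = reference(T(p))."""
    H, W = reference.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    sy, sx = transform.map_points(yy, xx, reference.shape)
    return ndimage.map_coordinates(reference, [sy, sx], order=3, mode="nearest")


class TestRigidTransform:
    def test_inverse_composes_to_identity(self):
        t = RigidTransform(3.7, -4.2, 1.9)
        c = t.compose(t.inverse())
        assert abs(c.theta_deg) < 1e-9
        assert abs(c.tx_px) < 1e-9 and abs(c.ty_px) < 1e-9

    def test_map_points_pure_translation(self):
        t = RigidTransform(0.0, 2.0, -3.0)
        y, x = t.map_points(np.array([5.0]), np.array([7.0]), (64, 64))
        assert (y[0], x[0]) == (2.0, 9.0)


class TestPairRegistration:
    def test_self_registration_is_identity(self, cone_phantom):
        t = register_rigid_pair(cone_phantom, cone_phantom)
        assert abs(t.theta_deg) < 1e-3
        assert abs(t.tx_px) < 1e-3 and abs(t.ty_px) < 1e-3

    @pytest.mark.parametrize(
        "true",
        [
            RigidTransform(0.0, -3.0, 2.0),   # reference shifted by (+3, -2)
            RigidTransform(1.0, 2.5, -1.25),  # rotation + sub-pixel shift
        ],
    )
    def test_known_transform_recovery(self, cone_phantom, true):
        src = warp_with(true, cone_phantom)
        rec = register_rigid_pair(src, cone_phantom)
        assert abs(rec.theta_deg - true.theta_deg) < 0.05
        assert abs(rec.tx_px - true.tx_px) < 0.1
        assert abs(rec.ty_px - true.ty_px) < 0.1

    def test_recovery_under_noise(self, cone_phantom, rng):
        true = RigidTransform(0.5, 1.7, -2.3)
        src = warp_with(true, cone_phantom) + rng.normal(0, 5, cone_phantom.shape)
        rec = register_rigid_pair(np.clip(src, 0, 255), cone_phantom)
        assert abs(rec.tx_px - true.tx_px) < 0.3
        assert abs(rec.ty_px - true.ty_px) < 0.3

    def test_constant_images_rejected(self):
        flat = np.full((64, 64), 50.0)
        with pytest.raises(ValueError):
            register_rigid_pair(flat, flat)

    def test_registration_does_not_increase_mse(self, cone_phantom):
        true = RigidTransform(0.8, 3.2, -2.1)
        src = warp_with(true, cone_phantom)
        rec = register_rigid_pair(src, cone_phantom)
        warped, mask = apply_rigid(src, rec)
        mse_before = np.mean((src - cone_phantom)[mask] ** 2)
        mse_after = np.mean((warped - cone_phantom)[mask] ** 2)
        assert mse_after <= mse_before


class TestLargestRectangle:
    def test_full_mask(self):
        r = largest_interior_rectangle(np.ones((10, 12), bool))
        assert (r.y0, r.x0, r.height, r.width) == (0, 0, 10, 12)

    def test_l_shaped_mask(self):
        mask = np.ones((10, 10), bool)
        mask[:5, :5] = False
        r = largest_interior_rectangle(mask)
        assert r.height * r.width == 50

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="excessive motion"):
            largest_interior_rectangle(np.zeros((5, 5), bool))


class TestStabilizeAndCrop:
    def test_zero_motion_full_crop_identity_transforms(self):
        # a truly static scene: no motion, no noise, no moving particles
        cfg = small_scene_config(noise_gaussian_sd=0.0, particle_density_per_100px=0.0)
        scene = generate_scene(cfg)
        stack, _ = render_video(scene, cfg, still_motion(), seed=0)
        reg, transforms, rect = stabilize_and_crop(stack)
        assert (rect.height, rect.width) == (96, 96)
        for t in transforms:
            assert abs(t.theta_deg) < 1e-3
            assert abs(t.tx_px) < 1e-2 and abs(t.ty_px) < 1e-2

    def test_bounded_translations_bound_the_crop(self, cone_phantom):
        shifts = [(0.0, 0.0), (4.0, -5.0), (-3.0, 2.0), (5.0, 5.0)]
        frames = [warp_with(RigidTransform(0, tx, ty), cone_phantom) for tx, ty in shifts]
        reg, transforms, rect = stabilize_and_crop(FrameStack(np.stack(frames)))
        assert rect.width >= 128 - 10
        assert rect.height >= 128 - 10

    def test_known_motion_residual_below_fifth_of_pixel(self):
        cfg = small_scene_config(width_px=128, height_px=128, noise_gaussian_sd=0.0)
        scene = generate_scene(cfg)
        motion = still_motion(rigid_translation_sd_px=3.0, rigid_rotation_sd_deg=0.3)
        stack, truth = render_video(scene, cfg, motion, seed=3)
        _, transforms, _ = stabilize_and_crop(stack)
        for rec, true in zip(transforms, truth.rigid_transforms):
            rms = transform_rms_difference(rec, true, (128, 128))
            assert rms < 0.2
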