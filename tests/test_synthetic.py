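import dataclasses

import numpy as np
import pytest

from aoslo.cnr import SQUARE_SIZE
from aoslo.synthetic import (
    MotionConfig,
    SceneConfig,
    default_roiset,
    generate_scene,
    render_video,
)
from tests.conftest import small_scene_config, still_motion


class TestConfigs:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(n_frames=1)
        with pytest.raises(ValueError):
            SceneConfig(vessel_shadow_factor=0.0)
        with pytest.raises(ValueError):
            SceneConfig(background_intensity=300)
        with pytest.raises(ValueError):
            MotionConfig(horizontal_anisotropy=0.5)
        with pytest.raises(ValueError):
            MotionConfig(rigid_translation_sd_px=-1)

    def test_vessel_too_wide_for_frame_rejected(self):
        with pytest.raises(ValueError, match="leave the image"):
            SceneConfig(width_px=40, height_px=40, vessel_width_px=9.0)


class TestGenerateScene:
    def test_shadow_darkens_vessel(self):
        scene = generate_scene(small_scene_config())
        inside = scene.base_image[scene.vessel_mask].mean()
        outside = scene.base_image[~scene.vessel_mask].mean()
        assert inside < outside

    def test_unit_shadow_factor_disables_shadow(self):
        cfg_on = small_scene_config()
        cfg_off = dataclasses.replace(cfg_on, vessel_shadow_factor=1.0)
        scene = generate_scene(cfg_off)
        inside = scene.base_image[scene.vessel_mask].mean()
        outside = scene.base_image[~scene.vessel_mask].mean()
        assert inside == pytest.approx(outside, rel=0.05)

    def test_deterministic_for_fixed_seed(self):
        a = generate_scene(small_scene_config())
        b = generate_scene(small_scene_config())
        np.testing.assert_array_equal(a.base_image, b.base_image)
        np.testing.assert_array_equal(a.vessel_mask, b.vessel_mask)

    def test_centerline_inside_mask(self):
        scene = generate_scene(small_scene_config())
        cl = scene.vessel_centerlines[0]
        iy = np.round(cl[:, 0]).astype(int)
        ix = np.round(cl[:, 1]).astype(int)
        assert scene.vessel_mask[iy, ix].all()


class TestRenderVideo:
    def test_motionless_noiseless_particle_free_frames_equal_base(self):
        cfg = small_scene_config(noise_gaussian_sd=0.0, particle_density_per_100px=0.0)
        scene = generate_scene(cfg)
        stack, truth = render_video(scene, cfg, still_motion(), seed=0)
        for frame in stack.frames:
            np.testing.assert_array_equal(frame, scene.base_image)
        np.testing.assert_array_equal(truth.displacement_fields, 0.0)

    def test_pure_translation_truth_field_constant(self):
        cfg = small_scene_config(noise_gaussian_sd=0.0)
        scene = generate_scene(cfg)
        motion = still_motion(rigid_translation_sd_px=5.0)
        stack, truth = render_video(scene, cfg, motion, seed=1)
        # intraframe field is zero; all displacement is in the rigid part
        np.testing.assert_array_equal(truth.displacement_fields, 0.0)
        assert any(not t.is_identity for t in truth.rigid_transforms[1:])
        assert truth.rigid_transforms[0].is_identity

    def test_full_length_video_has_per_frame_ground_truth(self):
        # native recording length: 64 frames at 32 Hz
        cfg = small_scene_config(width_px=64, height_px=64, n_frames=64,
                                 vessel_width_px=6.0)
        scene = generate_scene(cfg)
        stack, truth = render_video(scene, cfg, MotionConfig(), seed=2)
        assert stack.n_frames == 64
        assert len(truth.rigid_transforms) == 64
        assert truth.displacement_fields.shape == (64, 64, 64, 2)

    def test_determinism_bitwise(self):
        cfg = small_scene_config()
        scene = generate_scene(cfg)
        s1, _ = render_video(scene, cfg, MotionConfig(), seed=9)
        s2, _ = render_video(scene, cfg, MotionConfig(), seed=9)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_off_vessel_pixels_static_without_motion_or_noise(self):
        cfg = small_scene_config(noise_gaussian_sd=0.0)
        scene = generate_scene(cfg)
        stack, _ = render_video(scene, cfg, still_motion(), seed=3)
        off = ~scene.vessel_mask
        var = stack.frames.var(axis=0)
        np.testing.assert_array_equal(var[off], 0.0)

    def test_particles_painted_inside_vessel(self):
        cfg = small_scene_config(noise_gaussian_sd=0.0)
        scene = generate_scene(cfg)
        stack, truth = render_video(scene, cfg, still_motion(), seed=4)
        from aoslo.synthetic import _interp_centerline

        cl = scene.vessel_centerlines[0]
        for k in range(stack.n_frames):
            pts = _interp_centerline(cl, truth.particle_tracks[:, k])
            iy = np.round(pts[:, 0]).astype(int)
            ix = np.round(pts[:, 1]).astype(int)
            assert scene.vessel_mask[iy, ix].all()

    def test_excessive_particle_speed_rejected(self):
        cfg = small_scene_config(particle_speed_px_per_frame=5000.0)
        scene = generate_scene(cfg)
        with pytest.raises(ValueError, match="speed"):
            render_video(scene, cfg, still_motion(), seed=0)

    def test_reference_frame_has_zero_motion(self):
        cfg = small_scene_config()
        scene = generate_scene(cfg)
        _, truth = render_video(scene, cfg, MotionConfig(), seed=5)
        assert truth.rigid_transforms[0].is_identity
        np.testing.assert_array_equal(truth.displacement_fields[0], 0.0)


class TestDefaultROISet:
    def test_protocol_geometry(self):
        cfg = small_scene_config(width_px=128, height_px=128)
        scene = generate_scene(cfg)
        _, truth = render_video(scene, cfg, still_motion(), seed=6)
        rois = truth.roi_set
        assert len(rois.background_squares) == 6
        # squares disjoint from the vessel mask
        for x0, y0 in rois.background_squares:
            assert not scene.vessel_mask[y0 : y0 + SQUARE_SIZE, x0 : x0 + SQUARE_SIZE].any()
        # polyline vertices inside the vessel mask
        iy = np.round(rois.vessel_polyline[:, 1]).astype(int)
        ix = np.round(rois.vessel_polyline[:, 0]).astype(int)
        assert scene.vessel_mask[iy, ix].all()

    def test_cropped_field_offsets_coordinates(self):
        cfg = small_scene_config(width_px=128, height_px=128)
        scene = generate_scene(cfg)
        _, truth = render_video(scene, cfg, still_motion(), seed=6)
        rois = default_roiset(truth, (110, 112), origin=(9, 8))
        rois.validate_bounds((110, 112))
        # shifted polyline still lands inside the mask in scene coords
        iy = np.round(rois.vessel_polyline[:, 1] + 9).astype(int)
        ix = np.round(rois.vessel_polyline[:, 0] + 8).astype(int)
        assert scene.vessel_mask[iy, ix].all()

    def test_too_small_field_raises(self):
        cfg = small_scene_config(width_px=128, height_px=128)
        scene = generate_scene(cfg)
        _, truth = render_video(scene, cfg, still_motion(), seed=6)
        with pytest.raises(ValueError):
            default_roiset(truth, (30, 30), origin=(40, 40))
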