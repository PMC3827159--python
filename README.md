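# aoslo

Capillary visualization from adaptive-optics scanning laser
ophthalmoscopy (AO-SLO) video, for researchers working on retinal
microcirculation imaging. AO-SLO resolves single photoreceptors and the
bright blood cells (leukocytes / plasma gaps) moving through vessel
shadows, but the raw 2-s videos are corrupted by eye motion: whole-frame
shifts and rotations between frames, plus within-frame warps imprinted
by the raster scan. This package implements the full processing chain
that turns such a video into a perfusion map, and a synthetic retina
video generator with exact ground truth so every stage can be verified.

## Pipeline

1. **Desinusoiding** (optional) — resamples the fast scan axis to undo
   the nonuniform spatial sampling of the sinusoidally moving resonant
   scanner.
2. **Rigid stabilization** — every frame is registered to the first
   frame by sub-pixel minimization of the mean squared intensity
   difference (coarse-to-fine pyramid), then the stack is cropped to
   the largest rectangle valid in all frames.
3. **Elastic registration** — each frame is registered to the first
   frame with a consistent (bidirectional) cubic B-spline free-form
   deformation. For forward/backward deformations g_f, g_b the energy is

   E = w_img [MSE(S∘g_f, T) + MSE(T∘g_b, S)]
     + w_cons [mean‖g_f(g_b(p))−p‖² + mean‖g_b(g_f(p))−p‖²]
     + w_reg [bending(g_f) + bending(g_b)]

   minimized by L-BFGS over the control-point coefficients, refining
   both image resolution and control grid (4×4 → 8×8 → 16×16 intervals).
   A 64-frame video entails exactly 63 pairwise registrations against
   the fixed first-frame reference.
4. **Motion contrast** — division images D_k = I_{k+1}/I_k between
   sequential registered frames; the per-pixel variance over all D_k is
   the capillary map (static tissue ≈ 1 with low variance; moving blood
   cells fluctuate).
5. **CNR evaluation** — foreground = a polyline along the vessel shadow,
   background = six 20×20-px squares on the surrounding cone mosaic,
   both defined on the first frame and transferred unchanged;

   CNR = (f − b) / √(δf² + δb²).

Maps built without / with stage 3 are the E(−) / E(+) conditions; the
paired comparison of their CNRs quantifies what elastic registration
buys.

## Worked example

```python
from aoslo import (SceneConfig, MotionConfig, generate_scene, render_video,
                   stabilize_and_crop, stabilize_elastic, motion_contrast,
                   default_roiset, compute_cnr)

cfg = SceneConfig(width_px=128, height_px=128, n_frames=16, rng_seed=1)
scene = generate_scene(cfg)
stack, truth = render_video(scene, cfg, MotionConfig(), seed=1)

reg, transforms, crop = stabilize_and_crop(stack)
rois = default_roiset(truth, (crop.height, crop.width), origin=(crop.y0, crop.x0))

map_em = motion_contrast(reg)                      # E(-)
el, _ = stabilize_elastic(reg)
map_ep = motion_contrast(el)                       # E(+)
print(f"CNR E(-) = {compute_cnr(map_em, rois).cnr:.3f}")
print(f"CNR E(+) = {compute_cnr(map_ep, rois).cnr:.3f}")
```

Output (about 2 minutes on one CPU):

```
CNR E(-) = 1.043
CNR E(+) = 2.475
```

The E(−) map is washed out because uncorrected intraframe warps make
the cone mosaic itself flicker frame-to-frame, inflating the background
variance; after elastic registration the background settles and the
vessel stands out, roughly doubling the CNR.

The same flow is available from the shell:

```
aoslo simulate --seed 1 --out out/video
aoslo run out/video/video.tif --elastic --out out/eplus
aoslo experiment --n-videos 5 --seed 1 --out out/experiment
```

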