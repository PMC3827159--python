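"""Synthetic AO-SLO video generation with ground truth.

Emulates the statistical structure of a parafoveal AO-SLO recording
focused on the photoreceptor layer: a bright cone-mosaic background
(jittered hexagonal lattice of Gaussian spots), a dark vessel shadow
(smooth random centerline, multiplicative darkening), bright particles
(leukocytes / plasma gaps) advected along the vessel, interframe rigid
eye motion, intraframe B-spline raster warps with stronger horizontal
amplitude, optional sinusoidal fast-axis sampling, and Gaussian sensor
noise.

Per-frame composition order follows physical causality: particles are
painted on the static scene, the intraframe warp and the rigid motion
displace the retina, the scanner optionally resamples sinusoidally and
the sensor adds noise.  The first frame is rendered with zero rigid and
zero intraframe displacement, so the reference frame equals the
undistorted scene and ground-truth comparisons are exact.

Ground truth records exactly what was applied: the rigid transform and
the dense intraframe sampling displacement per frame (``frame(p) =
clean(p + d(p))``), particle tracks as centerline arc positions, and a
suggested ROI set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .cnr import N_SQUARES, SQUARE_SIZE, ROISet
from .elastic import BSplineDeformation
from .preprocess import ScanModel, resample_frame
from .rigid import FrameStack, RigidTransform

__all__ = [
    "SceneConfig",
    "MotionConfig",
    "StaticScene",
    "GroundTruth",
    "generate_scene",
    "render_video",
    "default_roiset",
]


@dataclass
class SceneConfig:
    """Static-scene and acquisition parameters.

    Defaults mirror the native acquisition geometry (400×400 px, 32 Hz,
    64 frames = 2 s); intensities are on the 0–255 gray scale.
    """

    width_px: int = 400
    height_px: int = 400
    n_frames: int = 64
    frame_rate_hz: float = 32.0
    cone_spacing_px: float = 6.0
    cone_radius_px: float = 1.6
    cone_peak_intensity: float = 110.0
    background_intensity: float = 100.0
    vessel_n_segments: int = 4
    vessel_width_px: float = 9.0
    vessel_shadow_factor: float = 0.35
    particle_density_per_100px: float = 2.0
    particle_speed_px_per_frame: float = 4.0
    particle_intensity: float = 190.0
    noise_gaussian_sd: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0 or self.n_frames < 2:
            raise ValueError("dimensions must be positive and n_frames >= 2")
        if not (0 < self.vessel_shadow_factor <= 1):
            raise ValueError("vessel_shadow_factor must be in (0, 1]")
        for name in ("cone_peak_intensity", "background_intensity", "particle_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must be in [0, 255]")
        if self.cone_spacing_px <= 0 or self.cone_radius_px <= 0 or self.vessel_width_px <= 0:
            raise ValueError("geometric scales must be positive")
        if self.noise_gaussian_sd < 0 or self.particle_density_per_100px < 0:
            raise ValueError("noise SD and particle density must be nonnegative")
        if min(self.width_px, self.height_px) < 6 * self.vessel_width_px:
            raise ValueError(
                "vessel geometry would leave the image: frame too small for "
                "the configured vessel width"
            )


@dataclass
class MotionConfig:
    """Interframe and intraframe motion amplitudes.

    Intraframe control-point displacements are drawn from
    N(0, amplitude²); the horizontal (x) component is scaled by
    ``horizontal_anisotropy`` (≥ 1) because raster scanning leaves far
    more distortion along the horizontal direction than the vertical.
    """

    rigid_translation_sd_px: float = 3.0
    rigid_rotation_sd_deg: float = 0.3
    intraframe_warp_amplitude_px: float = 3.0
    intraframe_grid: tuple[int, int] = (6, 6)
    horizontal_anisotropy: float = 2.0
    scan_model_enabled: bool = False

    def __post_init__(self) -> None:
        if (self.rigid_translation_sd_px < 0 or self.rigid_rotation_sd_deg < 0
                or self.intraframe_warp_amplitude_px < 0):
            raise ValueError("motion SDs must be nonnegative")
        if self.horizontal_anisotropy < 1:
            raise ValueError("horizontal_anisotropy must be >= 1")
        if min(self.intraframe_grid) < 1:
            raise ValueError("intraframe grid must have at least 1 interval per axis")


@dataclass
class StaticScene:
    """Motion- and noise-free base image plus vessel geometry."""

    base_image: np.ndarray
    vessel_centerlines: list[np.ndarray]  # each (N, 2) of (y, x), ~1 px arc spacing
    vessel_mask: np.ndarray


@dataclass
class GroundTruth:
    """Everything the generator applied, for use as registration and
    motion-contrast oracles."""

    rigid_transforms: list[RigidTransform]
    displacement_fields: np.ndarray  # (T, H, W, 2) of (dy, dx), sampling convention
    particle_tracks: np.ndarray      # (n_particles, T) arc positions on the centerline
    scene: StaticScene
    roi_set: ROISet | None = None

    def __post_init__(self) -> None:
        if len(self.rigid_transforms) != self.displacement_fields.shape[0]:
            raise ValueError("rigid transform count must match field count")
        if not np.all(np.isfinite(self.displacement_fields)):
            raise ValueError("non-finite ground-truth displacement field")


# ---------------------------------------------------------------------------
# static scene
# ---------------------------------------------------------------------------

def _make_centerline(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth random vessel centerline crossing the frame, (N, 2) of
    (y, x) resampled to ~1 px arc spacing."""
    H, W = cfg.height_px, cfg.width_px
    n_way = cfg.vessel_n_segments + 1
    xs = np.linspace(0, W - 1, n_way)
    y0 = rng.uniform(0.4, 0.6) * H
    offsets = np.cumsum(rng.normal(0.0, H / 10.0, n_way))
    offsets -= offsets.mean()
    margin = max(0.18 * H, cfg.vessel_width_px + SQUARE_SIZE / 2)
    ys = np.clip(y0 + offsets, margin, H - 1 - margin)
    spline = CubicSpline(xs, ys)
    xf = np.linspace(0, W - 1, 4 * W)
    yf = np.clip(spline(xf), margin, H - 1 - margin)
    pts = np.stack([yf, xf], axis=1)
    # arc-length resample to ~1 px spacing
    seg = np.hypot(np.diff(yf), np.diff(xf))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(arc[-1]), 2)
    s = np.linspace(0, arc[-1], n)
    return np.stack([np.interp(s, arc, pts[:, 0]), np.interp(s, arc, pts[:, 1])], axis=1)


def _paint_gaussian(img: np.ndarray, cy: float, cx: float, amp: float, sigma: float,
                    blend_to: float | None = None,
                    confine_to: np.ndarray | None = None) -> None:
    """Add (or blend toward ``blend_to``) a Gaussian spot in place,
    optionally confined to a boolean mask (particles never spill out of
    the vessel shadow)."""
    H, W = img.shape
    r = max(int(np.ceil(3 * sigma)), 1)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, H)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, W)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    if confine_to is not None:
        g = g * confine_to[y0:y1, x0:x1]
    if blend_to is None:
        img[y0:y1, x0:x1] += amp * g
    else:
        patch = img[y0:y1, x0:x1]
        img[y0:y1, x0:x1] = patch + (blend_to - patch) * np.clip(g, 0.0, 1.0)


def generate_scene(config: SceneConfig) -> StaticScene:
    """Build the motion-free, noise-free base image.

    Cone mosaic: hexagonal lattice at ``cone_spacing_px`` with per-cone
    positional jitter (uniform ±20 % of the spacing) and Gaussian
    profiles over a uniform background.  Vessel: a smooth random
    centerline rendered by distance thresholding; the shadow is a
    multiplicative darkening by ``vessel_shadow_factor`` with a ~1.5 px
    soft edge.  Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    H, W = config.height_px, config.width_px

    centerline = _make_centerline(config, rng)
    raster = np.zeros((H, W), dtype=bool)
    iy = np.clip(np.round(centerline[:, 0]).astype(int), 0, H - 1)
    ix = np.clip(np.round(centerline[:, 1]).astype(int), 0, W - 1)
    raster[iy, ix] = True
    dist = ndimage.distance_transform_edt(~raster)
    mask = dist <= config.vessel_width_px / 2.0

    base = np.full((H, W), config.background_intensity, dtype=np.float64)
    a = config.cone_spacing_px
    dy = a * np.sqrt(3) / 2.0
    row_ys = np.arange(-a, H + a, dy)
    for i, y in enumerate(row_ys):
        x_offset = (a / 2.0) if i % 2 else 0.0
        col_xs = np.arange(-a, W + a, a) + x_offset
        jit = rng.uniform(-0.2 * a, 0.2 * a, size=(len(col_xs), 2))
        for (jy, jx), x in zip(jit, col_xs):
            _paint_gaussian(base, y + jy, x + jx,
                            config.cone_peak_intensity, config.cone_radius_px)

    if config.vessel_shadow_factor < 1.0:
        edge = 1.5
        t = np.clip((dist - config.vessel_width_px / 2.0) / edge, 0.0, 1.0)
        base *= config.vessel_shadow_factor + (1.0 - config.vessel_shadow_factor) * t
    np.clip(base, 0.0, 255.0, out=base)
    return StaticScene(base_image=base, vessel_centerlines=[centerline], vessel_mask=mask)


# ---------------------------------------------------------------------------
# video rendering
# ---------------------------------------------------------------------------

def _interp_centerline(centerline: np.ndarray, arcpos: np.ndarray) -> np.ndarray:
    """Points (y, x) at given arc positions (1 px node spacing)."""
    idx = np.arange(len(centerline), dtype=np.float64)
    seg = np.hypot(*np.diff(centerline, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    y = np.interp(arcpos, arc, centerline[:, 0])
    x = np.interp(arcpos, arc, centerline[:, 1])
    return np.stack([y, x], axis=1)


def _centerline_length(centerline: np.ndarray) -> float:
    return float(np.hypot(*np.diff(centerline, axis=0).T).sum())


def render_video(
    scene: StaticScene,
    scene_cfg: SceneConfig,
    motion: MotionConfig,
    seed: int,
) -> tuple[FrameStack, GroundTruth]:
    """Render the video and record the applied motion as ground truth.

    Per frame: particles advance along the centerline and are painted
    as bright blobs inside the vessel; the intraframe B-spline warp and
    the rigid transform are applied in a single resampling pass
    (``frame(p) = img(T(p) + d(T(p)))`` with T the rigid source→reference
    map); optional sinusoidal fast-axis sampling; Gaussian noise; clip
    to [0, 255].
    """
    H, W = scene.base_image.shape
    if (scene_cfg.height_px, scene_cfg.width_px) != (H, W):
        raise ValueError("scene does not match scene_cfg dimensions")
    rng = np.random.default_rng(seed)
    T_frames = scene_cfg.n_frames
    centerline = scene.vessel_centerlines[0]
    length = _centerline_length(centerline)
    if scene_cfg.particle_speed_px_per_frame >= length:
        raise ValueError("particle speed exceeds vessel length per frame")

    n_part = max(1, int(round(scene_cfg.particle_density_per_100px * length / 100.0)))
    if scene_cfg.particle_density_per_100px == 0:
        n_part = 0
    pos0 = rng.uniform(0.0, length, n_part)
    p_sigma = max(0.8, 0.30 * scene_cfg.vessel_width_px)

    gy, gx = motion.intraframe_grid
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    frames = np.empty((T_frames, H, W))
    rigids: list[RigidTransform] = []
    fields = np.zeros((T_frames, H, W, 2), dtype=np.float64)
    tracks = np.zeros((n_part, T_frames))

    for k in range(T_frames):
        pos = (pos0 + k * scene_cfg.particle_speed_px_per_frame) % length
        tracks[:, k] = pos
        img = scene.base_image.copy()
        for cy, cx in _interp_centerline(centerline, pos):
            _paint_gaussian(img, cy, cx, 0.0, p_sigma,
                            blend_to=scene_cfg.particle_intensity,
                            confine_to=scene.vessel_mask)

        if k == 0:
            rigid = RigidTransform()
            out = img
        else:
            cy_coef = rng.normal(0.0, motion.intraframe_warp_amplitude_px, (gy + 3, gx + 3))
            cx_coef = rng.normal(
                0.0,
                motion.intraframe_warp_amplitude_px * motion.horizontal_anisotropy,
                (gy + 3, gx + 3),
            )
            theta = rng.normal(0.0, motion.rigid_rotation_sd_deg)
            tx, ty = rng.normal(0.0, motion.rigid_translation_sd_px, 2)
            rigid = RigidTransform(theta, tx, ty)
            deform = BSplineDeformation(gy + 3, gx + 3, cy_coef, cx_coef, H, W)
            dy, dx = deform.dense_field()
            fields[k, :, :, 0] = dy
            fields[k, :, :, 1] = dx
            if np.abs(cy_coef).max() == 0 and np.abs(cx_coef).max() == 0 and rigid.is_identity:
                out = img
            else:
                ry, rx = rigid.map_points(yy, xx, (H, W))
                ddy, ddx = deform.displacement_at(ry, rx)
                pref = ndimage.spline_filter(img, order=3, mode="nearest")
                out = ndimage.map_coordinates(
                    pref, [ry + ddy, rx + ddx], order=3, prefilter=False, mode="nearest"
                )
        rigids.append(rigid)

        if motion.scan_model_enabled:
            out = resample_frame(out, ScanModel())
        if scene_cfg.noise_gaussian_sd > 0:
            out = out + rng.normal(0.0, scene_cfg.noise_gaussian_sd, (H, W))
        frames[k] = np.clip(out, 0.0, 255.0)

    stack = FrameStack(frames, scene_cfg.frame_rate_hz)
    truth = GroundTruth(rigids, fields, tracks, scene)
    try:
        truth.roi_set = default_roiset(truth, (H, W))
    except ValueError:
        truth.roi_set = None  # frame too small for the full ROI protocol
    return stack, truth


# ---------------------------------------------------------------------------
# ROI suggestion
# ---------------------------------------------------------------------------

def default_roiset(
    truth: GroundTruth,
    shape: tuple[int, int],
    origin: tuple[int, int] = (0, 0),
) -> ROISet:
    """Build the ROI protocol from ground truth for a (possibly
    cropped) field: the vessel polyline restricted to the field, and
    six 20×20-px background squares adjacent to but disjoint from the
    vessel mask.

    ``shape`` is the field's (H, W); ``origin`` its (y0, x0) offset in
    scene coordinates (the crop offset).  Raises if six disjoint
    off-vessel squares cannot be placed.
    """
    Hc, Wc = shape
    oy, ox = origin
    scene = truth.scene
    centerline = scene.vessel_centerlines[0]

    inset = 2
    sel = (
        (centerline[:, 0] >= oy + inset) & (centerline[:, 0] <= oy + Hc - 1 - inset)
        & (centerline[:, 1] >= ox + inset) & (centerline[:, 1] <= ox + Wc - 1 - inset)
    )
    if sel.sum() < 2:
        raise ValueError("vessel centerline does not cross the cropped field")
    idx = np.flatnonzero(sel)
    # longest contiguous run inside the field
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    run = max(runs, key=len)
    pts = centerline[run][:: max(1, len(run) // 40)]
    if len(pts) < 2:
        pts = centerline[run][[0, -1]]
    poly_xy = np.stack([pts[:, 1] - ox, pts[:, 0] - oy], axis=1)

    mask_c = scene.vessel_mask[oy : oy + Hc, ox : ox + Wc]
    if mask_c.shape != (Hc, Wc):
        raise ValueError("field extends beyond the scene")
    # integral image for O(1) square emptiness tests
    I = np.zeros((Hc + 1, Wc + 1), dtype=np.int64)
    I[1:, 1:] = np.cumsum(np.cumsum(mask_c.astype(np.int64), axis=0), axis=1)
    dist = ndimage.distance_transform_edt(~mask_c)

    def square_sum(r, c):
        s = SQUARE_SIZE
        return I[r + s, c + s] - I[r, c + s] - I[r + s, c] + I[r, c]

    s = SQUARE_SIZE
    step = 2
    cand = []
    for r in range(0, Hc - s + 1, step):
        for c in range(0, Wc - s + 1, step):
            if square_sum(r, c) == 0:
                cand.append((dist[r + s // 2, c + s // 2], r, c))
    cand.sort()

    for adj_max in (2.5 * s, 4.0 * s, np.inf):
        chosen: list[tuple[int, int]] = []
        for d, r, c in cand:
            if d > adj_max:
                break
            if all(abs(r - r2) >= s or abs(c - c2) >= s for c2, r2 in chosen):
                chosen.append((c, r))  # stored as (top_left_x, top_left_y)
            if len(chosen) == N_SQUARES:
                break
        if len(chosen) == N_SQUARES:
            return ROISet(vessel_polyline=poly_xy, background_squares=chosen)
    raise ValueError("cannot place 6 disjoint off-vessel background squares")
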