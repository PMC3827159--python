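"""Sub-pixel rigid-body stabilization of an AO-SLO frame stack.

Interframe eye motion shifts and rotates whole frames between raster
scans.  This module aligns every frame of a stack to the first frame by
minimizing the mean squared intensity difference over a coarse-to-fine
image pyramid, then crops the stack to the largest axis-aligned
rectangle that is valid (i.e. sampled from inside the source) in every
registered frame.

Coordinate convention: x = column, y = row, origin at pixel (0, 0),
pixel centers at integer coordinates.  A :class:`RigidTransform` maps
source-frame coordinates to reference-frame coordinates; rotation is
about the image center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import rescale

logger = logging.getLogger("aoslo.rigid")

__all__ = [
    "FrameStack",
    "RigidTransform",
    "RigidOpts",
    "CropRect",
    "register_rigid_pair",
    "stabilize_and_crop",
    "apply_rigid",
    "transform_rms_difference",
    "largest_interior_rectangle",
]


@dataclass
class FrameStack:
    """Ordered grayscale frames (T, H, W), values in [0, 255].

    Frames are held as floating point internally; 8-bit quantization
    only happens on file output.
    """

    frames: np.ndarray
    frame_rate_hz: float = 32.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frames.shape[0] < 2:
            raise ValueError("a stack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class RigidTransform:
    """Rigid-body motion: rotation by ``theta_deg`` about the image
    center followed by translation ``(tx_px, ty_px)``.

    Maps source coordinates to reference coordinates:
    ``p_ref = R(p_src - c) + c + t``.
    """

    theta_deg: float = 0.0
    tx_px: float = 0.0
    ty_px: float = 0.0
    converged: bool = True

    CONVENTION = "source->reference; x=column, y=row; rotation about image center"

    def map_points(self, y, x, shape):
        """Apply the transform to (y, x) points; ``shape`` fixes the
        rotation center."""
        cy = (shape[0] - 1) / 2.0
        cx = (shape[1] - 1) / 2.0
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        xr = c * (x - cx) - s * (y - cy) + cx + self.tx_px
        yr = s * (x - cx) + c * (y - cy) + cy + self.ty_px
        return yr, xr

    def inverse(self) -> "RigidTransform":
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        # p_src = R^-1 (p_ref - c0 - t) + c0; rewrite as rotation about
        # center followed by translation R^-1(-t).
        txi = -(c * self.tx_px + s * self.ty_px)
        tyi = -(-s * self.tx_px + c * self.ty_px)
        return RigidTransform(-self.theta_deg, txi, tyi, self.converged)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        tx = c * other.tx_px - s * other.ty_px + self.tx_px
        ty = s * other.tx_px + c * other.ty_px + self.ty_px
        return RigidTransform(self.theta_deg + other.theta_deg, tx, ty)

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.theta_deg) < 1e-12
            and abs(self.tx_px) < 1e-12
            and abs(self.ty_px) < 1e-12
        )

    def to_dict(self) -> dict:
        return {
            "theta_deg": float(self.theta_deg),
            "tx_px": float(self.tx_px),
            "ty_px": float(self.ty_px),
            "convention": self.CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["theta_deg"], d["tx_px"], d["ty_px"])


@dataclass
class RigidOpts:
    """Optimizer settings for rigid registration."""

    n_levels: int = 3
    max_iter: int = 50
    param_tol: float = 1e-4  # px / deg
    use_phase_corr_init: bool = True


@dataclass
class CropRect:
    y0: int
    x0: int
    height: int
    width: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width)


def apply_rigid(image: np.ndarray, transform: RigidTransform, order: int = 3):
    """Resample ``image`` (a source frame) into reference coordinates.

    Backward warping: ``out(p) = image(T^-1(p))``.  Returns the warped
    image and a validity mask of pixels sampled from inside the source.
    Out-of-bounds samples are filled with the image mean (they are
    excluded from any MSE through the mask).
    """
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    inv = transform.inverse()
    sy, sx = inv.map_points(yy, xx, image.shape)
    # valid = sampled within the source pixel footprint (half-pixel slack,
    # so sub-millipixel registration jitter cannot shave off border rows)
    mask = (sy >= -0.5) & (sy <= H - 0.5) & (sx >= -0.5) & (sx <= W - 0.5)
    warped = ndimage.map_coordinates(image, [sy, sx], order=order, mode="nearest")
    warped = np.where(mask, warped, image.mean())
    return warped, mask


def _masked_mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    n = int(mask.sum())
    if n == 0:
        return np.inf
    d = (a - b)[mask]
    return float(np.dot(d, d) / n)


def _pyramid(image: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Finest-first list of anti-aliased half-resolution images."""
    levels = [np.asarray(image, dtype=np.float64)]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        if min(prev.shape) < 24:
            break
        levels.append(rescale(prev, 0.5, anti_aliasing=True, order=3, mode="reflect"))
    return levels


def register_rigid_pair(
    source: np.ndarray,
    reference: np.ndarray,
    opts: RigidOpts | None = None,
) -> RigidTransform:
    """Estimate the rigid-body transform aligning ``source`` to
    ``reference`` by sub-pixel MSE minimization.

    The mean squared intensity difference over the overlap region is
    minimized coarse-to-fine on an image pyramid, with cubic-spline
    interpolated intensities, so the optimum is located with sub-pixel
    accuracy.  If no improvement over the identity is found, the
    identity is returned with ``converged=False``.
    """
    opts = opts or RigidOpts()
    source = np.asarray(source, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if source.shape != reference.shape:
        raise ValueError("source and reference must have the same shape")
    if np.ptp(source) == 0 or np.ptp(reference) == 0:
        raise ValueError("cannot register constant images")

    src_levels = _pyramid(source, opts.n_levels)
    ref_levels = _pyramid(reference, opts.n_levels)
    n_levels = len(src_levels)

    # params at the coarsest level; translations are in that level's px
    theta, tx, ty = 0.0, 0.0, 0.0
    if opts.use_phase_corr_init:
        shift, _, _ = phase_cross_correlation(
            ref_levels[-1], src_levels[-1], upsample_factor=8, normalization=None
        )
        # moving shifted by `shift` matches reference -> T(p) = p + t
        ty, tx = float(shift[0]), float(shift[1])

    for lv in range(n_levels - 1, -1, -1):
        src, ref = src_levels[lv], ref_levels[lv]
        pref = ndimage.spline_filter(src, order=3, mode="nearest")
        H, W = src.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

        def mse_of(params) -> float:
            t = RigidTransform(params[0], params[1], params[2])
            inv = t.inverse()
            sy, sx = inv.map_points(yy, xx, src.shape)
            mask = (sy >= 0) & (sy <= H - 1) & (sx >= 0) & (sx <= W - 1)
            n = int(mask.sum())
            if n < 16:
                return np.inf
            warped = ndimage.map_coordinates(
                pref, [sy, sx], order=3, prefilter=False, mode="nearest"
            )
            d = (warped - ref)[mask]
            return float(np.dot(d, d) / n)

        x0 = np.array([theta, tx, ty])
        res = minimize(
            mse_of,
            x0,
            method="Powell",
            options={
                "xtol": opts.param_tol,
                "ftol": 1e-10,
                "maxiter": opts.max_iter,
            },
        )
        if lv == n_levels - 1 and res.fun > mse_of(np.zeros(3)):
            warnings.warn(
                "rigid registration failed to improve over identity at the "
                "coarsest level; returning identity",
                stacklevel=2,
            )
            return RigidTransform(converged=False)
        theta, tx, ty = res.x
        if lv > 0:  # translations double at the next finer level
            tx *= src_levels[lv - 1].shape[1] / W
            ty *= src_levels[lv - 1].shape[0] / H

    return RigidTransform(float(theta), float(tx), float(ty))


def largest_interior_rectangle(mask: np.ndarray) -> CropRect:
    """Maximal axis-aligned rectangle of True pixels (histogram DP)."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    heights = np.zeros(W, dtype=np.int64)
    best = CropRect(0, 0, 0, 0)
    best_area = 0
    for r in range(H):
        heights = (heights + 1) * mask[r]
        stack: list[int] = []
        i = 0
        while i <= W:
            h = heights[i] if i < W else 0
            if not stack or heights[stack[-1]] <= h:
                stack.append(i)
                i += 1
            else:
                top = stack.pop()
                hh = int(heights[top])
                left = stack[-1] + 1 if stack else 0
                area = hh * (i - left)
                if area > best_area:
                    best_area = area
                    best = CropRect(r - hh + 1, left, hh, i - left)
    if best_area == 0:
        raise ValueError("excessive motion: no common valid region to crop to")
    return best


def stabilize_and_crop(
    stack: FrameStack, opts: RigidOpts | None = None
) -> tuple[FrameStack, list[RigidTransform], CropRect]:
    """Register every frame to the first frame and crop to the common
    valid region.

    Each frame is resampled into the reference (first) frame's
    coordinates; the per-frame validity masks are intersected and the
    maximal axis-aligned rectangle inside the intersection becomes the
    crop window applied to all frames.
    """
    opts = opts or RigidOpts()
    T = stack.n_frames
    ref = stack.frames[0]
    transforms: list[RigidTransform] = [RigidTransform()]
    registered = [ref.copy()]
    common = np.ones(ref.shape, dtype=bool)
    for k in range(1, T):
        t = register_rigid_pair(stack.frames[k], ref, opts)
        transforms.append(t)
        if t.is_identity:
            registered.append(stack.frames[k].copy())
        else:
            warped, mask = apply_rigid(stack.frames[k], t)
            common &= mask
            registered.append(warped)
        logger.debug("rigid frame %d: %s", k, t.to_dict())
    rect = largest_interior_rectangle(common)
    sl = rect.slices()
    cropped = np.stack([f[sl] for f in registered])
    out = FrameStack(cropped, stack.frame_rate_hz)
    logger.info(
        "rigid stabilization: %d frames, crop %dx%d at (%d,%d)",
        T, rect.height, rect.width, rect.y0, rect.x0,
    )
    return out, transforms, rect


def transform_rms_difference(
    t1: RigidTransform, t2: RigidTransform, shape: tuple[int, int]
) -> float:
    """RMS over the pixel grid of the displacement difference between
    two rigid maps — the registration residual against ground truth."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    y1, x1 = t1.map_points(yy, xx, shape)
    y2, x2 = t2.map_points(yy, xx, shape)
    return float(np.sqrt(np.mean((y1 - y2) ** 2 + (x1 - x2) ** 2)))
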