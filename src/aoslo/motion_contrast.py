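"""Motion-contrast capillary mapping.

Blood cells moving through vessel shadows change pixel intensities
between consecutive frames of a registered stack, while static tissue
does not.  Dividing each frame by its predecessor gives division images
that hover near 1 over static retina and fluctuate where cells move;
the per-pixel variance over all division images is the capillary map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigid import FrameStack

__all__ = ["MotionContrastMap", "division_images", "variance_map", "motion_contrast"]


@dataclass
class MotionContrastMap:
    """Per-pixel population variance of sequential division images.

    ``values`` is the raw variance map (nonnegative, float);
    ``display`` its 8-bit rendering after percentile clipping.
    """

    values: np.ndarray
    display: np.ndarray
    n_frames_used: int
    epsilon_used: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("variance map must be finite and nonnegative")


def division_images(stack: FrameStack, epsilon: float = 1.0) -> np.ndarray:
    """Ratios of sequential frames: D_k = I_{k+1} / max(I_k, epsilon).

    The denominator floor (default 1 gray level) prevents blow-ups in
    dark vessel shadows; the ratio is computed in real arithmetic on the
    registered stack.  Returns a (T−1, H, W) array.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    f = stack.frames
    return f[1:] / np.maximum(f[:-1], epsilon)


def variance_map(
    ratio_stack: np.ndarray,
    display_clip_percentiles: tuple[float, float] = (1.0, 99.0),
) -> MotionContrastMap:
    """Per-pixel population variance over the division images.

    The display rendering linearly rescales the variance to 0–255 after
    clipping at the given percentiles (default 1st/99th) of the map.
    """
    ratio_stack = np.asarray(ratio_stack, dtype=np.float64)
    if ratio_stack.ndim != 3 or ratio_stack.shape[0] < 2:
        raise ValueError("need at least 2 ratio images")
    values = ratio_stack.var(axis=0)  # population variance
    lo, hi = np.percentile(values, display_clip_percentiles)
    if hi > lo:
        disp = (np.clip(values, lo, hi) - lo) / (hi - lo) * 255.0
    else:
        disp = np.zeros_like(values)
    display = np.round(disp).astype(np.uint8)
    return MotionContrastMap(
        values=values,
        display=display,
        n_frames_used=ratio_stack.shape[0] + 1,
        epsilon_used=float("nan"),
    )


def motion_contrast(
    stack: FrameStack,
    epsilon: float = 1.0,
    display_clip_percentiles: tuple[float, float] = (1.0, 99.0),
) -> MotionContrastMap:
    """Convenience: division images then variance map."""
    m = variance_map(division_images(stack, epsilon), display_clip_percentiles)
    m.epsilon_used = float(epsilon)
    return m
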