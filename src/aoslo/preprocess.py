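"""Desinusoiding: forward model and correction of sinusoidal fast-axis
sampling.

A resonant scanner sweeps the fast (horizontal) axis sinusoidally, so
pixels acquired at uniform time intervals sample the retina nonuniformly
— densely near the turnaround edges, sparsely at the center.  The
forward model here maps uniform time samples to spatial positions on
the cosine trajectory; desinusoiding interpolates each row back onto
the uniform integer grid.

There is no scanner calibration input: the model is parameterized only
by the fraction of the half-period used for imaging (``scan_fraction``),
and the correction exactly inverts this module's own forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .rigid import FrameStack

__all__ = ["ScanModel", "sample_positions", "resample_frame", "desinusoid_frame", "desinusoid_stack"]


@dataclass
class ScanModel:
    fast_axis: str = "horizontal"
    scan_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.fast_axis != "horizontal":
            raise ValueError("only a horizontal fast axis is supported")
        if not (0 < self.scan_fraction <= 1):
            raise ValueError("scan_fraction must be in (0, 1]")


def sample_positions(width_px: int, model: ScanModel) -> np.ndarray:
    """Spatial positions of the ``width_px`` uniform time samples.

    Time samples s_i cover the central ``scan_fraction`` of the half
    period [0, 1]; position follows x = (W−1)(1 − cos(π s))/2 and is
    min–max renormalized to span exactly [0, W−1].  Positions are
    strictly increasing (the cosine is monotone on (0, π)).
    """
    if width_px < 2:
        raise ValueError("width_px must be at least 2")
    f = model.scan_fraction
    s = 0.5 + f * (np.arange(width_px) / (width_px - 1) - 0.5)
    x = (width_px - 1) * (1.0 - np.cos(np.pi * s)) / 2.0
    x -= x[0]
    x *= (width_px - 1) / x[-1]
    return x


def resample_frame(frame: np.ndarray, model: ScanModel) -> np.ndarray:
    """Forward model: sample a uniformly-gridded frame on the sinusoidal
    trajectory (what the scanner records)."""
    frame = np.asarray(frame, dtype=np.float64)
    pos = sample_positions(frame.shape[1], model)
    spl = CubicSpline(np.arange(frame.shape[1]), frame, axis=1)
    return spl(pos)


def desinusoid_frame(frame: np.ndarray, model: ScanModel | None) -> np.ndarray:
    """Resample each row from the sinusoidal positions back onto the
    uniform integer grid (cubic interpolation, clipped to [0, 255]).

    ``model=None`` is the degenerate pass-through: the frame is assumed
    already uniform and returned unchanged.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if model is None:
        return frame.copy()
    pos = sample_positions(frame.shape[1], model)
    spl = CubicSpline(pos, frame, axis=1)
    out = spl(np.arange(frame.shape[1], dtype=np.float64))
    return np.clip(out, 0.0, 255.0)


def desinusoid_stack(stack: FrameStack, model: ScanModel | None) -> FrameStack:
    frames = np.stack([desinusoid_frame(f, model) for f in stack.frames])
    return FrameStack(frames, stack.frame_rate_hz)
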