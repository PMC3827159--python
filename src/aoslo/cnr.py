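"""Contrast-to-noise ratio of capillary maps and the paired E(−)/E(+)
comparison.

The ROI protocol: a polyline traced along the vessel shadow on the
first (reference) frame is the foreground; six 20×20-px squares on the
surrounding cone mosaic are the background.  Because the map shares the
first frame's coordinates, the ROIs transfer unchanged.  Quality is

    CNR = (f − b) / sqrt(δf² + δb²)

with f, b the foreground/background means and δf, δb their standard
deviations, evaluated on the 8-bit display rendering of the map.  CNR
is invariant under positive affine rescaling of the display, so the
rendering choice cannot change conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.draw import line as _bresenham_line

from .motion_contrast import MotionContrastMap

__all__ = [
    "SQUARE_SIZE",
    "N_SQUARES",
    "ROISet",
    "CNRResult",
    "ComparisonStats",
    "rasterize_polyline",
    "compute_cnr",
    "compare_paired",
]

SQUARE_SIZE = 20
N_SQUARES = 6


@dataclass
class ROISet:
    """Foreground vessel polyline and six 20×20 background squares.

    ``vessel_polyline`` is an (N, 2) array of (x, y) vertices;
    ``background_squares`` a list of six (top_left_x, top_left_y)
    integer pairs, all in first-frame (post-crop) coordinates.
    """

    vessel_polyline: np.ndarray
    background_squares: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.vessel_polyline = np.asarray(self.vessel_polyline, dtype=np.float64)
        if self.vessel_polyline.ndim != 2 or self.vessel_polyline.shape[1] != 2:
            raise ValueError("vessel_polyline must be an (N, 2) array of (x, y)")
        if self.vessel_polyline.shape[0] < 2:
            raise ValueError("vessel_polyline needs at least 2 vertices")
        if len(self.background_squares) != N_SQUARES:
            raise ValueError(f"exactly {N_SQUARES} background squares are required")
        self.background_squares = [(int(x), int(y)) for x, y in self.background_squares]
        for i, (x0, y0) in enumerate(self.background_squares):
            for x1, y1 in self.background_squares[i + 1 :]:
                if abs(x0 - x1) < SQUARE_SIZE and abs(y0 - y1) < SQUARE_SIZE:
                    raise ValueError("background squares must be mutually disjoint")

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        H, W = shape
        xs, ys = self.vessel_polyline[:, 0], self.vessel_polyline[:, 1]
        if xs.min() < 0 or ys.min() < 0 or xs.max() > W - 1 or ys.max() > H - 1:
            raise ValueError("vessel polyline extends out of bounds")
        for x0, y0 in self.background_squares:
            if x0 < 0 or y0 < 0 or x0 + SQUARE_SIZE > W or y0 + SQUARE_SIZE > H:
                raise ValueError("background square extends out of bounds")

    def to_dict(self) -> dict:
        return {
            "vessel_polyline": self.vessel_polyline.tolist(),
            "background_squares": [list(s) for s in self.background_squares],
            "square_size": SQUARE_SIZE,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROISet":
        return cls(np.array(d["vessel_polyline"]), [tuple(s) for s in d["background_squares"]])


@dataclass
class CNRResult:
    """Foreground/background statistics and the resulting CNR."""

    f: float
    b: float
    delta_f: float
    delta_b: float
    cnr: float
    n_fg_pixels: int
    n_bg_pixels: int


@dataclass
class ComparisonStats:
    """Paired E(−)/E(+) summary: per-condition mean ± SD of CNR,
    per-pair ratios, and the two-sided paired-t p-value."""

    n_pairs: int
    mean_eminus: float
    sd_eminus: float
    mean_eplus: float
    sd_eplus: float
    ratios: np.ndarray
    mean_ratio: float
    sd_ratio: float
    t_stat: float
    p_value: float


def rasterize_polyline(polyline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """1-px-wide Bresenham rasterization; returns unique (row, col)
    pixel coordinates as an (M, 2) int array."""
    pts = np.round(np.asarray(polyline, dtype=np.float64)).astype(int)
    rr_all, cc_all = [], []
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = _bresenham_line(y0, x0, y1, x1)
        rr_all.append(rr)
        cc_all.append(cc)
    rr = np.concatenate(rr_all)
    cc = np.concatenate(cc_all)
    pix = np.unique(np.stack([rr, cc], axis=1), axis=0)
    if (pix[:, 0].min() < 0 or pix[:, 1].min() < 0
            or pix[:, 0].max() >= shape[0] or pix[:, 1].max() >= shape[1]):
        raise ValueError("rasterized polyline leaves the image")
    return pix


def compute_cnr(map_or_image, rois: ROISet) -> CNRResult:
    """CNR of a capillary map for one ROI set.

    Accepts a :class:`MotionContrastMap` (its display rendering is
    used, consistent with reading gray values off the 8-bit image) or a
    plain 2-D array.  Background statistics are pooled over all six
    squares.  Standard deviations are population SDs; a fully constant
    map (δf = δb = 0) is defined to have CNR 0.
    """
    if isinstance(map_or_image, MotionContrastMap):
        img = map_or_image.display.astype(np.float64)
    else:
        img = np.asarray(map_or_image, dtype=np.float64)
    rois.validate_bounds(img.shape)
    line_pix = rasterize_polyline(rois.vessel_polyline, img.shape)
    line_set = {(int(r), int(c)) for r, c in line_pix}
    bg_vals = []
    for x0, y0 in rois.background_squares:
        for r in range(y0, y0 + SQUARE_SIZE):
            for c in range(x0, x0 + SQUARE_SIZE):
                if (r, c) in line_set:
                    raise ValueError(
                        "invalid ROI set: background square overlaps the vessel line"
                    )
        bg_vals.append(img[y0 : y0 + SQUARE_SIZE, x0 : x0 + SQUARE_SIZE].ravel())
    fg = img[line_pix[:, 0], line_pix[:, 1]]
    bg = np.concatenate(bg_vals)
    f, b = float(fg.mean()), float(bg.mean())
    df, db = float(fg.std()), float(bg.std())  # population SDs
    denom = np.sqrt(df * df + db * db)
    cnr = 0.0 if denom == 0 else (f - b) / denom
    return CNRResult(f, b, df, db, float(cnr), fg.size, bg.size)


def compare_paired(pairs: list[tuple[CNRResult, CNRResult]]) -> ComparisonStats:
    """Paired comparison of (E(−), E(+)) CNR results matched by video
    and ROI set.

    Summary means/SDs use the sample SD (ddof=1), matching how cohort
    tables report mean ± SD; the p-value is a two-sided paired t-test.
    Identical conditions (all differences zero) yield p = 1.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for a paired comparison")
    em = np.array([p[0].cnr for p in pairs], dtype=np.float64)
    ep = np.array([p[1].cnr for p in pairs], dtype=np.float64)
    if np.any(em == 0):
        raise ValueError("E(-) CNR of 0 makes the pair ratio undefined")
    ratios = ep / em
    diff = ep - em
    if np.allclose(diff, 0.0, atol=1e-12):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(ep, em)
    return ComparisonStats(
        n_pairs=len(pairs),
        mean_eminus=float(em.mean()),
        sd_eminus=float(em.std(ddof=1)),
        mean_eplus=float(ep.mean()),
        sd_eplus=float(ep.std(ddof=1)),
        ratios=ratios,
        mean_ratio=float(ratios.mean()),
        sd_ratio=float(ratios.std(ddof=1)),
        t_stat=float(t_stat),
        p_value=float(p),
    )
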