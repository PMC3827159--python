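"""Consistent (bidirectional) B-spline elastic registration.

Intraframe eye motion warps each raster-scanned frame relative to the
reference; a rigid model cannot correct it.  This module estimates a
free-form deformation parameterized by cubic B-spline control points,
registering each frame of a stack to the first frame.

Two deformations are estimated simultaneously per pair — source→target
(forward) and target→source (backward) — and the energy couples them:

    E = w_image · [ MSE(deform(S, fw), T) + MSE(deform(T, bw), S) ]
      + w_consistency · [ mean ‖fw(bw(p)) − p‖² + mean ‖bw(fw(p)) − p‖² ]
      + w_regularization · [ bending(fw) + bending(bw) ]

where bending is the integral of squared second-order partials of the
displacement.  The consistency terms penalize the pair for failing to
be mutual inverses, which suppresses the registration error a single
one-way deformation accumulates.  Minimization is quasi-Newton
(L-BFGS-B) on the concatenated control coefficients, coarse-to-fine
over both an image pyramid and a control-grid refinement schedule.

Displacements are in pixels of the frame geometry they are attached to.
A deformation maps position p to p + d(p) and images are backward
warped: out(p) = in(p + d(p)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.transform import rescale

from .rigid import FrameStack

logger = logging.getLogger("aoslo.elastic")

__all__ = [
    "BSplineDeformation",
    "EnergyWeights",
    "ElasticOpts",
    "deform_image",
    "register_elastic_pair",
    "stabilize_elastic",
    "composition_residual",
]


# ---------------------------------------------------------------------------
# cubic B-spline basis
# ---------------------------------------------------------------------------

def bspline3(t: np.ndarray) -> np.ndarray:
    """Centered cubic B-spline, support (-2, 2), partition of unity on
    the integer shifts."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    m = t < 1
    out[m] = (4.0 - 6.0 * t[m] ** 2 + 3.0 * t[m] ** 3) / 6.0
    m = (t >= 1) & (t < 2)
    out[m] = (2.0 - t[m]) ** 3 / 6.0
    return out


_BASIS_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _basis_matrix(n: int, g: int) -> np.ndarray:
    """(n, g+3) matrix B[i, k] = B3(x_i/h - (k-1)) with h = (n-1)/g.

    Control point k=0..g+2 covers the domain with one ring of border
    padding; zero coefficients give the identity map.
    """
    key = (n, g)
    B = _BASIS_CACHE.get(key)
    if B is None:
        h = (n - 1) / g
        u = np.arange(n, dtype=np.float64) / h
        k = np.arange(g + 3, dtype=np.float64)
        B = bspline3(u[:, None] - (k[None, :] - 1.0))
        _BASIS_CACHE[key] = B
    return B


def _eval_coeffs(C: np.ndarray, uy: np.ndarray, ux: np.ndarray) -> np.ndarray:
    """Evaluate a coefficient grid at arbitrary normalized positions
    (uy = y/h_y, ux = x/h_x, both in [0, g])."""
    gy = C.shape[0] - 3
    gx = C.shape[1] - 3
    uy = np.clip(uy, 0.0, gy)
    ux = np.clip(ux, 0.0, gx)
    ky0 = np.floor(uy).astype(np.intp)
    kx0 = np.floor(ux).astype(np.intp)
    val = np.zeros_like(uy)
    for jy in range(4):
        ky = ky0 + jy
        wy = bspline3(uy - ky + 1.0)
        kyc = np.minimum(ky, C.shape[0] - 1)  # weight is 0 where clipped
        for jx in range(4):
            kx = kx0 + jx
            wx = bspline3(ux - kx + 1.0)
            kxc = np.minimum(kx, C.shape[1] - 1)
            val += wy * wx * C[kyc, kxc]
    return val


def _scatter_coeffs(
    vals: np.ndarray, uy: np.ndarray, ux: np.ndarray, gy: int, gx: int
) -> np.ndarray:
    """Adjoint of :func:`_eval_coeffs`: accumulate ``vals`` onto the
    coefficient grid with the same basis weights."""
    uy = np.clip(np.ravel(uy), 0.0, gy)
    ux = np.clip(np.ravel(ux), 0.0, gx)
    v = np.ravel(vals)
    ky0 = np.floor(uy).astype(np.intp)
    kx0 = np.floor(ux).astype(np.intp)
    ncols = gx + 3
    size = (gy + 3) * ncols
    acc = np.zeros(size)
    for jy in range(4):
        ky = ky0 + jy
        wy = bspline3(uy - ky + 1.0)
        kyc = np.minimum(ky, gy + 2)
        for jx in range(4):
            kx = kx0 + jx
            wx = bspline3(ux - kx + 1.0)
            kxc = np.minimum(kx, gx + 2)
            acc += np.bincount(kyc * ncols + kxc, weights=wy * wx * v, minlength=size)
    return acc.reshape(gy + 3, ncols)


@dataclass
class BSplineDeformation:
    """Free-form deformation d(p) on an H×W image, parameterized by
    control-point displacement coefficients on a padded grid.

    ``grid_rows``/``grid_cols`` count control points *including* the
    border padding; the interior grid has ``grid_rows - 3`` ×
    ``grid_cols - 3`` spline intervals.  ``coef_y``/``coef_x`` are the
    displacement coefficients in pixels.
    """

    grid_rows: int
    grid_cols: int
    coef_y: np.ndarray
    coef_x: np.ndarray
    image_height: int
    image_width: int

    def __post_init__(self) -> None:
        self.coef_y = np.asarray(self.coef_y, dtype=np.float64)
        self.coef_x = np.asarray(self.coef_x, dtype=np.float64)
        if self.coef_y.shape != (self.grid_rows, self.grid_cols):
            raise ValueError("coef_y shape does not match grid dims")
        if self.coef_x.shape != (self.grid_rows, self.grid_cols):
            raise ValueError("coef_x shape does not match grid dims")
        if not (np.all(np.isfinite(self.coef_y)) and np.all(np.isfinite(self.coef_x))):
            raise ValueError("non-finite deformation coefficients")

    @classmethod
    def identity(cls, intervals: tuple[int, int], shape: tuple[int, int]):
        gy, gx = intervals
        z = np.zeros((gy + 3, gx + 3))
        return cls(gy + 3, gx + 3, z.copy(), z.copy(), shape[0], shape[1])

    @property
    def intervals(self) -> tuple[int, int]:
        return self.grid_rows - 3, self.grid_cols - 3

    def dense_field(self) -> tuple[np.ndarray, np.ndarray]:
        """(dy, dx) displacement on the full pixel grid."""
        gy, gx = self.intervals
        By = _basis_matrix(self.image_height, gy)
        Bx = _basis_matrix(self.image_width, gx)
        dy = By @ self.coef_y @ Bx.T
        dx = By @ self.coef_x @ Bx.T
        return dy, dx

    def displacement_at(self, y: np.ndarray, x: np.ndarray):
        """(dy, dx) at arbitrary (possibly non-integer) positions."""
        gy, gx = self.intervals
        hy = (self.image_height - 1) / gy
        hx = (self.image_width - 1) / gx
        uy = np.asarray(y, dtype=np.float64) / hy
        ux = np.asarray(x, dtype=np.float64) / hx
        return _eval_coeffs(self.coef_y, uy, ux), _eval_coeffs(self.coef_x, uy, ux)

    def mean_abs_displacement(self) -> float:
        dy, dx = self.dense_field()
        return float(np.mean(np.hypot(dy, dx)))

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "coef_y": self.coef_y.tolist(),
            "coef_x": self.coef_x.tolist(),
            "image_height": self.image_height,
            "image_width": self.image_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineDeformation":
        return cls(
            d["grid_rows"], d["grid_cols"],
            np.array(d["coef_y"]), np.array(d["coef_x"]),
            d["image_height"], d["image_width"],
        )


@dataclass
class EnergyWeights:
    """Relative weights of the registration energy terms.

    The image term operates on intensities normalized to [0, 1], the
    consistency term on squared pixel distances, the regularization on
    squared second differences of the displacement (px⁻¹ units).
    """

    w_image: float = 1.0
    w_consistency: float = 1.0
    w_regularization: float = 0.1

    def __post_init__(self) -> None:
        if self.w_image <= 0:
            raise ValueError("w_image must be positive")
        if self.w_consistency < 0 or self.w_regularization < 0:
            raise ValueError("weights must be nonnegative")


@dataclass
class ElasticOpts:
    """Coarse-to-fine schedule and optimizer settings.

    ``schedule`` is a sequence of (downscale, grid_intervals) pairs,
    coarse first: the image is processed at 1/downscale resolution with
    the given number of spline intervals per axis.
    """

    schedule: tuple[tuple[int, int], ...] = ((4, 4), (2, 8), (1, 16))
    max_iter: int = 60
    ftol: float = 1e-9
    min_level_size: int = 12

    def effective_schedule(self, shape: tuple[int, int]):
        """Drop levels too coarse for the image; always keep the
        full-resolution level."""
        out = []
        for scale, g in self.schedule:
            n = min(shape) // scale
            if scale > 1 and (n < self.min_level_size or (n - 1) / g < 1.5):
                continue
            out.append((scale, g))
        if not out or out[-1][0] != 1:
            out.append(self.schedule[-1] if self.schedule[-1][0] == 1 else (1, 8))
        return out


def deform_image(image: np.ndarray, deformation: BSplineDeformation, order: int = 3):
    """Backward-warp ``image`` by a deformation: out(p) = in(p + d(p)).

    Returns the warped image and a validity mask flagging pixels whose
    sample point fell inside the input.  Intensities are clipped to the
    input's [min, max] to suppress cubic overshoot.
    """
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape
    if (deformation.image_height, deformation.image_width) != (H, W):
        raise ValueError("deformation domain does not match image shape")
    dy, dx = deformation.dense_field()
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    sy, sx = yy + dy, xx + dx
    mask = (sy >= 0) & (sy <= H - 1) & (sx >= 0) & (sx <= W - 1)
    warped = ndimage.map_coordinates(image, [sy, sx], order=order, mode="nearest")
    np.clip(warped, image.min(), image.max(), out=warped)
    return warped, mask


def composition_residual(
    fw: BSplineDeformation, truth_dy: np.ndarray, truth_dx: np.ndarray, border: int = 8
):
    """Endpoint error of recovered-then-true mapping against identity.

    The generator distorts a clean frame by backward warping with a
    ground-truth field d_true (frame(p) = clean(p + d_true(p))).  A
    perfect recovery satisfies d_fw(p) + d_true(p + d_fw(p)) = 0; the
    returned array is the magnitude of that residual on the interior
    (``border`` px excluded).
    """
    H, W = fw.image_height, fw.image_width
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    dfy, dfx = fw.dense_field()
    qy, qx = yy + dfy, xx + dfx
    ty = ndimage.map_coordinates(truth_dy, [qy, qx], order=1, mode="nearest")
    tx = ndimage.map_coordinates(truth_dx, [qy, qx], order=1, mode="nearest")
    res = np.hypot(dfy + ty, dfx + tx)
    if border:
        res = res[border:-border, border:-border]
    return res


# ---------------------------------------------------------------------------
# pair registration
# ---------------------------------------------------------------------------

def _bending_energy_and_grad(d: np.ndarray):
    """Mean squared second differences (xx, yy, 2·xy) and gradient."""
    H, W = d.shape
    n = H * W
    dxx = d[:, 2:] - 2.0 * d[:, 1:-1] + d[:, :-2]
    dyy = d[2:, :] - 2.0 * d[1:-1, :] + d[:-2, :]
    dxy = d[1:, 1:] - d[1:, :-1] - d[:-1, 1:] + d[:-1, :-1]
    e = (np.sum(dxx**2) + np.sum(dyy**2) + 2.0 * np.sum(dxy**2)) / n
    g = np.zeros_like(d)
    a = 2.0 / n
    g[:, 2:] += a * dxx
    g[:, 1:-1] -= 2.0 * a * dxx
    g[:, :-2] += a * dxx
    g[2:, :] += a * dyy
    g[1:-1, :] -= 2.0 * a * dyy
    g[:-2, :] += a * dyy
    b = 4.0 / n
    g[1:, 1:] += b * dxy
    g[1:, :-1] -= b * dxy
    g[:-1, 1:] += b * dxy
    g[:-1, :-1] -= b * dxy
    return e, g


class _PairLevel:
    """Energy/gradient of one (image level, grid level) problem."""

    def __init__(self, S, T, g, weights):
        self.S = S / 255.0
        self.T = T / 255.0
        self.g = g
        self.w = weights
        self.H, self.W = S.shape
        self.hy = (self.H - 1) / g
        self.hx = (self.W - 1) / g
        self.By = _basis_matrix(self.H, g)
        self.Bx = _basis_matrix(self.W, g)
        self.S_pref = ndimage.spline_filter(self.S, order=3, mode="nearest")
        self.T_pref = ndimage.spline_filter(self.T, order=3, mode="nearest")
        self.gSy, self.gSx = np.gradient(self.S)
        self.gTy, self.gTx = np.gradient(self.T)
        self.yy, self.xx = np.mgrid[0 : self.H, 0 : self.W].astype(np.float64)
        self.n_coef = (g + 3) * (g + 3)

    def unpack(self, c):
        k = self.n_coef
        s = self.g + 3
        return [c[i * k : (i + 1) * k].reshape(s, s) for i in range(4)]

    def _project(self, dense):
        return self.By.T @ dense @ self.Bx

    def _image_term(self, d_y, d_x, src_pref, tgt, gsy, gsx):
        qy = self.yy + d_y
        qx = self.xx + d_x
        mask = (qy >= 0) & (qy <= self.H - 1) & (qx >= 0) & (qx <= self.W - 1)
        n = max(int(mask.sum()), 1)
        w = ndimage.map_coordinates(src_pref, [qy, qx], order=3, prefilter=False, mode="nearest")
        r = np.where(mask, w - tgt, 0.0)
        e = float(np.sum(r * r) / n)
        gy_at = ndimage.map_coordinates(gsy, [qy, qx], order=1, mode="nearest")
        gx_at = ndimage.map_coordinates(gsx, [qy, qx], order=1, mode="nearest")
        s = (2.0 / n) * r
        return e, self._project(s * gy_at), self._project(s * gx_at)

    def _consistency_term(self, Cay, Cax, day, dax, dby, dbx):
        """Residual of a∘b against identity: r(p) = d_b(p) + d_a(p + d_b(p)).

        ``day/dax`` and ``dby/dbx`` are the precomputed dense fields of
        the two deformations; returns the energy and gradients w.r.t.
        both coefficient sets.
        """
        H, W, g = self.H, self.W, self.g
        qy = self.yy + dby
        qx = self.xx + dbx
        uy = np.clip(qy, 0, H - 1) / self.hy
        ux = np.clip(qx, 0, W - 1) / self.hx
        ry = dby + _eval_coeffs(Cay, uy, ux)
        rx = dbx + _eval_coeffs(Cax, uy, ux)
        n = H * W
        e = float((np.sum(ry * ry) + np.sum(rx * rx)) / n)
        s = 2.0 / n
        gCay = _scatter_coeffs(s * ry, uy, ux, g, g)
        gCax = _scatter_coeffs(s * rx, uy, ux, g, g)
        # chain through q = p + d_b(p): Jacobian of d_a sampled at q
        Jy = np.gradient(day)
        Jx = np.gradient(dax)
        Jyy = ndimage.map_coordinates(Jy[0], [qy, qx], order=1, mode="nearest")
        Jyx = ndimage.map_coordinates(Jy[1], [qy, qx], order=1, mode="nearest")
        Jxy = ndimage.map_coordinates(Jx[0], [qy, qx], order=1, mode="nearest")
        Jxx = ndimage.map_coordinates(Jx[1], [qy, qx], order=1, mode="nearest")
        gby = s * (ry * (1.0 + Jyy) + rx * Jxy)
        gbx = s * (ry * Jyx + rx * (1.0 + Jxx))
        return e, gCay, gCax, self._project(gby), self._project(gbx)

    def energy_and_grad(self, c):
        Cfy, Cfx, Cby, Cbx = self.unpack(c)
        dfy = self.By @ Cfy @ self.Bx.T
        dfx = self.By @ Cfx @ self.Bx.T
        dby = self.By @ Cby @ self.Bx.T
        dbx = self.By @ Cbx @ self.Bx.T

        w = self.w
        gC = [np.zeros_like(Cfy) for _ in range(4)]

        e_img = 0.0
        e, gy, gx = self._image_term(dfy, dfx, self.S_pref, self.T, self.gSy, self.gSx)
        e_img += e
        gC[0] += w.w_image * gy
        gC[1] += w.w_image * gx
        e, gy, gx = self._image_term(dby, dbx, self.T_pref, self.S, self.gTy, self.gTx)
        e_img += e
        gC[2] += w.w_image * gy
        gC[3] += w.w_image * gx

        e_cons = 0.0
        if w.w_consistency > 0:
            # fw(bw(p)) - p
            e, gfy, gfx, gby, gbx = self._consistency_term(Cfy, Cfx, dfy, dfx, dby, dbx)
            e_cons += e
            gC[0] += w.w_consistency * gfy
            gC[1] += w.w_consistency * gfx
            gC[2] += w.w_consistency * gby
            gC[3] += w.w_consistency * gbx
            # bw(fw(p)) - p
            e, gby, gbx, gfy, gfx = self._consistency_term(Cby, Cbx, dby, dbx, dfy, dfx)
            e_cons += e
            gC[2] += w.w_consistency * gby
            gC[3] += w.w_consistency * gbx
            gC[0] += w.w_consistency * gfy
            gC[1] += w.w_consistency * gfx

        e_reg = 0.0
        if w.w_regularization > 0:
            for i, dense in enumerate((dfy, dfx, dby, dbx)):
                e, gdense = _bending_energy_and_grad(dense)
                e_reg += e
                gC[i] += w.w_regularization * self._project(gdense)

        total = w.w_image * e_img + w.w_consistency * e_cons + w.w_regularization * e_reg
        grad = np.concatenate([g.ravel() for g in gC])
        return total, grad


def _fit_coefficients(dense: np.ndarray, g: int) -> np.ndarray:
    """Least-squares B-spline coefficients reproducing a dense field."""
    H, W = dense.shape
    By = _basis_matrix(H, g)
    Bx = _basis_matrix(W, g)
    Ay = By.T @ By + 1e-9 * np.eye(g + 3)
    Ax = Bx.T @ Bx + 1e-9 * np.eye(g + 3)
    M = By.T @ dense @ Bx
    C = np.linalg.solve(Ay, M)
    return np.linalg.solve(Ax, C.T).T


def _transfer_coeffs(C: np.ndarray, old_shape, new_shape, new_g: int, axis: str) -> np.ndarray:
    """Carry coefficients to a new image size and/or grid resolution.

    The basis lives on normalized coordinates, so resizing only rescales
    the displacement values; changing the grid refits the dense field.
    """
    old_g = C.shape[0] - 3
    ratio = ((new_shape[0] - 1) / (old_shape[0] - 1) if axis == "y"
             else (new_shape[1] - 1) / (old_shape[1] - 1))
    By = _basis_matrix(new_shape[0], old_g)
    Bx = _basis_matrix(new_shape[1], old_g)
    dense = ratio * (By @ C @ Bx.T)
    if new_g == old_g and new_shape == old_shape:
        return ratio * C
    return _fit_coefficients(dense, new_g)


def register_elastic_pair(
    source: np.ndarray,
    target: np.ndarray,
    weights: EnergyWeights | None = None,
    opts: ElasticOpts | None = None,
):
    """Consistent elastic registration of one image pair.

    Returns ``(fw, bw, energy_trace)``: the forward deformation (warp
    ``source`` to look like ``target``), the backward deformation, and
    the accepted-energy trace across all levels (non-increasing within
    each level).
    """
    weights = weights or EnergyWeights()
    opts = opts or ElasticOpts()
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if source.shape != target.shape:
        raise ValueError("source and target must have the same shape")
    H, W = source.shape

    schedule = opts.effective_schedule(source.shape)
    coeffs = None      # [Cfy, Cfx, Cby, Cbx]
    prev_shape = None
    trace: list[list[float]] = []  # accepted energies, one list per level
    n_levels_failed = 0

    for li, (scale, g) in enumerate(schedule):
        if scale > 1:
            S = rescale(source, 1.0 / scale, anti_aliasing=True, order=3, mode="reflect")
            T = rescale(target, 1.0 / scale, anti_aliasing=True, order=3, mode="reflect")
        else:
            S, T = source, target
        lvl = _PairLevel(S, T, g, weights)
        shape = S.shape

        if coeffs is None:
            coeffs = [np.zeros((g + 3, g + 3)) for _ in range(4)]
        else:
            coeffs = [
                _transfer_coeffs(C, prev_shape, shape, g, axis)
                for C, axis in zip(coeffs, ("y", "x", "y", "x"))
            ]

        x0 = np.concatenate([C.ravel() for C in coeffs])
        e0, _ = lvl.energy_and_grad(x0)
        if not np.isfinite(e0):
            raise FloatingPointError("non-finite registration energy at start of level")
        lvl_trace = [e0]
        last_eval: dict[bytes, float] = {}

        def fun(c):
            e, grd = lvl.energy_and_grad(c)
            if not np.isfinite(e):
                raise FloatingPointError("non-finite registration energy")
            if len(last_eval) > 8:
                last_eval.clear()
            last_eval[c.tobytes()] = e
            return e, grd

        def cb(xk):
            e = last_eval.get(xk.tobytes())
            if e is not None:
                lvl_trace.append(min(e, lvl_trace[-1]))

        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B", callback=cb,
            options={"maxiter": opts.max_iter, "ftol": opts.ftol, "gtol": 1e-9},
        )
        if res.fun <= e0:
            coeffs = lvl.unpack(res.x)
            coeffs = [c.copy() for c in coeffs]
            lvl_trace.append(min(float(res.fun), lvl_trace[-1]))
        else:
            # line search found no acceptable step at this level (the
            # landscape can be flat enough that gradient approximation
            # error dominates); keep the incoming coefficients and let
            # the finer levels, where the signal is stronger, proceed
            n_levels_failed += 1
        trace.append(lvl_trace)
        prev_shape = shape
        logger.debug(
            "elastic level %d (1/%d, grid %d): E %.3e -> %.3e, %d it",
            li, scale, g, e0, min(res.fun, e0), res.nit,
        )

    if n_levels_failed == len(schedule) or coeffs is None:
        warnings.warn(
            "elastic registration found no improvement at any level; "
            "returning identity deformations",
            stacklevel=2,
        )
        g = schedule[-1][1]
        ident = BSplineDeformation.identity((g, g), (H, W))
        return ident, BSplineDeformation.identity((g, g), (H, W)), trace

    if prev_shape != (H, W):  # final level was not full resolution
        coeffs = [
            _transfer_coeffs(C, prev_shape, (H, W), schedule[-1][1], axis)
            for C, axis in zip(coeffs, ("y", "x", "y", "x"))
        ]
    g = coeffs[0].shape[0] - 3
    fw = BSplineDeformation(g + 3, g + 3, coeffs[0], coeffs[1], H, W)
    bw = BSplineDeformation(g + 3, g + 3, coeffs[2], coeffs[3], H, W)
    return fw, bw, trace


def stabilize_elastic(
    stack: FrameStack,
    weights: EnergyWeights | None = None,
    opts: ElasticOpts | None = None,
) -> tuple[FrameStack, list[BSplineDeformation]]:
    """Register frames 2..T of a rigid-registered stack to the first
    frame — exactly T−1 pairwise registrations — and replace each by its
    forward-deformed image.  The first frame is the fixed reference and
    is returned unchanged."""
    T = stack.n_frames
    ref = stack.frames[0]
    out = [ref.copy()]
    deformations: list[BSplineDeformation] = []
    for k in range(1, T):
        try:
            fw, _, _ = register_elastic_pair(stack.frames[k], ref, weights, opts)
            warped, _ = deform_image(stack.frames[k], fw)
        except Exception as exc:  # annotate with the frame index
            raise RuntimeError(f"elastic registration failed at frame {k}: {exc}") from exc
        out.append(warped)
        deformations.append(fw)
        logger.debug("elastic frame %d/%d: mean |d| = %.3f px",
                     k, T - 1, fw.mean_abs_displacement())
    logger.info("elastic stabilization: %d pairwise registrations", T - 1)
    return FrameStack(np.stack(out), stack.frame_rate_hz), deformations
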