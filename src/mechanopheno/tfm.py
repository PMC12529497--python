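"""Traction force microscopy: PIV displacement + Fourier-transform traction
cytometry (FTTC).

The measurement chain turns a pair (or stack) of fluorescent-bead images —
a cell-loaded frame and a cell-free reference — into a cell traction map:

1. ``align_to_reference``: rigid drift correction by phase correlation.
2. ``piv_displacement``: windowed normalized cross-correlation with
   three-point Gaussian subpixel peak fitting and a normalized-median
   outlier test.
3. ``fttc_traction``: inversion of the Boussinesq elastic half-space
   problem in Fourier space with zeroth-order Tikhonov regularization.
4. ``summarize_traction``: spatial median per frame, then temporal mean —
   the scalar traction readout.

The substrate is modelled as an incompressible (``nu = 0.5``) linearly
elastic half-space; for in-plane tractions ``t(k)`` the surface
displacement is ``u(k) = G(k) t(k)`` with the Green's tensor

    G(k) = 2 (1+nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2, -nu kx ky],
                                 [-nu kx ky, (1-nu) k^2 + nu kx^2]]

The zero-frequency (net-force) component is unobservable and pinned to 0;
physically admissible cell traction fields are force-balanced anyway.
Lengths are micrometres, stresses pascals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.registration import phase_cross_correlation

__all__ = [
    "DisplacementField", "TractionField", "TractionSummary", "BeadImagePair",
    "align_to_reference", "piv_displacement", "forward_displacement",
    "fttc_traction", "summarize_traction", "lcurve_lambda", "DEFAULT_LAMBDA",
]

# Tikhonov weight in (um/Pa)^2, chosen on the synthetic bead-image suite at
# default PIV settings as the discrepancy-principle point where the
# forward-model residual meets the PIV noise floor (see docs/methods.md).
DEFAULT_LAMBDA = 3e-8


@dataclass(frozen=True)
class BeadImagePair:
    """Cell-free reference plus one deformed frame (or a time series)."""

    reference: np.ndarray
    deformed: np.ndarray          # 2-D frame or 3-D (t, y, x) stack
    pixel_size: float             # um / pixel
    time_interval: float | None = None   # min, for series

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        def_ = np.asarray(self.deformed, dtype=float)
        if ref.ndim != 2:
            raise ValueError("reference must be a 2-D image")
        if def_.shape[-2:] != ref.shape:
            raise ValueError("reference and deformed must share frame shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "deformed", def_)

    def frames(self):
        d = self.deformed
        return d[None] if d.ndim == 2 else d


@dataclass(frozen=True)
class DisplacementField:
    """In-plane displacement vectors on a regular grid (um)."""

    grid_x: np.ndarray            # 1-D node x coordinates (um)
    grid_y: np.ndarray            # 1-D node y coordinates (um)
    u: np.ndarray                 # (ny, nx) x-displacement (um)
    v: np.ndarray                 # (ny, nx) y-displacement (um)
    valid_mask: np.ndarray        # (ny, nx) bool, False where replaced

    def __post_init__(self):
        for name in ("grid_x", "grid_y", "u", "v", "valid_mask"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.u.shape != (len(self.grid_y), len(self.grid_x)):
            raise ValueError("u shape must be (len(grid_y), len(grid_x))")
        if self.v.shape != self.u.shape or self.valid_mask.shape != self.u.shape:
            raise ValueError("u, v, valid_mask must share shape")
        for g in (self.grid_x, self.grid_y):
            if len(g) > 1:
                sp = np.diff(g)
                if not np.allclose(sp, sp[0], rtol=1e-8, atol=1e-12):
                    raise ValueError("grid must be uniformly spaced")

    @property
    def spacing(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0])

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass(frozen=True)
class TractionField:
    """Traction stress vectors (Pa) on the displacement grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    t_x: np.ndarray
    t_y: np.ndarray
    E_gel: float
    poisson: float = 0.5
    regularization: float = 0.0

    def __post_init__(self):
        for name in ("grid_x", "grid_y", "t_x", "t_y"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if self.t_x.shape != (len(self.grid_y), len(self.grid_x)):
            raise ValueError("t_x shape must be (len(grid_y), len(grid_x))")
        if self.t_y.shape != self.t_x.shape:
            raise ValueError("t_x and t_y must share shape")
        if self.E_gel <= 0:
            raise ValueError("E_gel must be positive")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

    @property
    def spacing(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0])

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t_x, self.t_y)


@dataclass(frozen=True)
class TractionSummary:
    """Per-frame spatial medians of |t| and their temporal mean (Pa)."""

    frame_medians: np.ndarray
    temporal_mean: float
    mask_id: str | None = None


# ---------------------------------------------------------------------------
# alignment


def align_to_reference(series: np.ndarray, reference: np.ndarray,
                       upsample_factor: int = 20,
                       max_shift_fraction: float = 0.25):
    """Rigidly register each frame to the cell-free reference.

    Per-frame translation is estimated by phase correlation (subpixel via
    Fourier upsampling), frames are shifted onto the reference grid, and
    everything is cropped to the overlap common to all frames.

    Returns ``(aligned_stack, cropped_reference, shifts)`` where ``shifts``
    is an (n, 2) array of applied (dy, dx) in pixels.
    """
    reference = np.asarray(reference, dtype=float)
    series = np.asarray(series, dtype=float)
    if series.ndim == 2:
        series = series[None]
    if series.shape[-2:] != reference.shape:
        raise ValueError("frame shape must match reference shape")

    shifts = np.zeros((len(series), 2))
    aligned = np.empty_like(series)
    limit = max_shift_fraction * np.array(reference.shape)
    for i, frame in enumerate(series):
        shift, _, _ = phase_cross_correlation(
            reference, frame, upsample_factor=upsample_factor,
            normalization=None)
        if np.any(np.abs(shift) > limit):
            raise RuntimeError(
                f"frame {i}: estimated shift {tuple(shift)} exceeds "
                f"{max_shift_fraction:.0%} of the image extent; "
                "alignment failure")
        shifts[i] = shift
        aligned[i] = (frame if np.all(shift == 0)
                      else ndi.shift(frame, shift, order=1, mode="nearest"))

    m_lo = np.ceil(np.maximum(shifts.max(axis=0), 0)).astype(int)
    m_hi = np.ceil(np.maximum(-shifts.min(axis=0), 0)).astype(int)
    sl = (slice(m_lo[0], reference.shape[0] - m_hi[0] or None),
          slice(m_lo[1], reference.shape[1] - m_hi[1] or None))
    return aligned[(slice(None),) + sl], reference[sl], shifts


# ---------------------------------------------------------------------------
# PIV


def _subpixel_quadratic(cc: np.ndarray, pk: tuple[int, int],
                        r: int = 2) -> tuple[np.ndarray, bool]:
    """Subpixel peak by least-squares log-Gaussian surface fit.

    Fits a 2-D quadratic to ``log c`` on the (2r+1)^2 neighborhood of the
    integer peak; the analytic maximum of the paraboloid is the offset.
    Averaging over the neighborhood suppresses the correlation pedestal of
    finite bead fields.  Returns ((dy, dx), ok); callers fall back to the
    per-axis 3-point fit when the surface is not a well-formed peak.
    """
    if (pk[0] - r < 0 or pk[0] + r >= cc.shape[0]
            or pk[1] - r < 0 or pk[1] + r >= cc.shape[1]):
        return np.zeros(2), False
    patch = cc[pk[0] - r:pk[0] + r + 1, pk[1] - r:pk[1] + r + 1]
    if np.any(patch <= 0):
        return np.zeros(2), False
    ys, xs = np.mgrid[-r:r + 1, -r:r + 1]
    z = np.log(patch).ravel()
    A = np.column_stack([np.ones_like(z), xs.ravel(), ys.ravel(),
                         xs.ravel()**2, ys.ravel()**2, (xs * ys).ravel()])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    _, cx, cy, cxx, cyy, cxy = coef
    H = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
    if cxx >= 0 or cyy >= 0 or np.linalg.det(H) <= 0:
        return np.zeros(2), False
    off = -np.linalg.solve(H, np.array([cx, cy]))   # (dx, dy)
    if np.any(np.abs(off) > r):
        return np.zeros(2), False
    return off[::-1], True


def _subpixel_offset(c: np.ndarray, peak: tuple[int, int]) -> np.ndarray:
    """3-point Gaussian (log-parabolic) peak interpolation per axis."""
    out = np.zeros(2)
    for ax in range(2):
        idx = [peak[0], peak[1]]
        lo, hi = idx.copy(), idx.copy()
        lo[ax] -= 1
        hi[ax] += 1
        if lo[ax] < 0 or hi[ax] >= c.shape[ax]:
            continue
        cm, c0, cp = c[tuple(lo)], c[tuple(peak)], c[tuple(hi)]
        if cm > 0 and c0 > 0 and cp > 0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
            denom = lm - 2 * l0 + lp
            if denom < 0:
                out[ax] = 0.5 * (lm - lp) / denom
        else:  # parabolic fallback when the Gaussian log is undefined
            denom = cm - 2 * c0 + cp
            if denom < 0:
                out[ax] = 0.5 * (cm - cp) / denom
        out[ax] = np.clip(out[ax], -1, 1)
    return out


def _normalized_median_test(u: np.ndarray, v: np.ndarray,
                            threshold: float = 2.0,
                            eps: float = 0.1) -> np.ndarray:
    """Universal outlier detection against the 8-neighbor median.

    Returns a boolean mask of outlier nodes.  ``eps`` (px) regularizes the
    residual normalization in quiescent regions.
    """
    bad = np.zeros(u.shape, dtype=bool)
    ny, nx = u.shape
    for comp in (u, v):
        for i in range(ny):
            for j in range(nx):
                nb = [comp[ii, jj]
                      for ii in range(max(i - 1, 0), min(i + 2, ny))
                      for jj in range(max(j - 1, 0), min(j + 2, nx))
                      if (ii, jj) != (i, j)]
                nb = np.asarray(nb)
                med = np.median(nb)
                rm = np.median(np.abs(nb - med))
                resid = np.abs(comp[i, j] - med) / (rm + eps)
                if resid > threshold:
                    bad[i, j] = True
    return bad


def piv_displacement(pair: BeadImagePair, window: int = 32,
                     overlap: float = 0.5,
                     outlier_threshold: float = 2.0) -> DisplacementField:
    """Displacement field from one bead-image pair by windowed PIV.

    Interrogation windows of ``window`` px (spaced by
    ``window * (1 - overlap)``) are cross-correlated between reference and
    deformed images (overlap-corrected, so finite-window taper does not
    bias peaks toward zero); the correlation peak is located to subpixel
    precision by a Gaussian peak fit (least-squares log-Gaussian surface,
    falling back to the per-axis 3-point fit).  Outliers flagged by the normalized
    median test (8 neighbors, threshold 2) are replaced by the local median
    and marked False in ``valid_mask``.
    """
    if window < 16:
        raise ValueError("window must be >= 16 px")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    ref, frames = pair.reference, pair.frames()
    if len(frames) != 1:
        raise ValueError("piv_displacement expects a single deformed frame; "
                         "loop over frames for a series")
    img = frames[0]
    H, W = ref.shape
    if window > min(H, W):
        raise ValueError("window larger than image")
    step = max(int(round(window * (1 - overlap))), 1)
    ys = np.arange(0, H - window + 1, step)
    xs = np.arange(0, W - window + 1, step)

    # unbiased correlation: divide each lag by its overlap area, removing
    # the triangular taper of finite windows that biases peaks toward 0
    lag = np.arange(-(window - 1), window)
    taper = ((window - np.abs(lag))[:, None] *
             (window - np.abs(lag))[None, :]).astype(float)
    m = window // 2   # search radius; larger shifts belong to alignment
    ctr = window - 1

    u = np.zeros((len(ys), len(xs)))
    v = np.zeros_like(u)
    valid = np.ones(u.shape, dtype=bool)
    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            a = ref[y0:y0 + window, x0:x0 + window]
            b = img[y0:y0 + window, x0:x0 + window]
            a = a - a.mean()
            b = b - b.mean()
            na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
            if na < 1e-12 or nb < 1e-12:   # empty / saturated window
                valid[iy, ix] = False
                continue
            c = fftconvolve(b, a[::-1, ::-1], mode="full") / (na * nb)
            c *= (window * window) / taper
            cc = c[ctr - m:ctr + m + 1, ctr - m:ctr + m + 1]
            peak = np.unravel_index(np.argmax(cc), cc.shape)
            d = np.array(peak, dtype=float) - m
            off, ok = _subpixel_quadratic(cc, peak)
            d += off if ok else _subpixel_offset(cc, peak)
            v[iy, ix], u[iy, ix] = d  # (dy, dx)

    bad = _normalized_median_test(u, v, threshold=outlier_threshold) | ~valid
    if bad.any():
        med_u = ndi.median_filter(u, size=3, mode="nearest")
        med_v = ndi.median_filter(v, size=3, mode="nearest")
        u = np.where(bad, med_u, u)
        v = np.where(bad, med_v, v)
    px = pair.pixel_size
    return DisplacementField(
        grid_x=(xs + (window - 1) / 2.0) * px,
        grid_y=(ys + (window - 1) / 2.0) * px,
        u=u * px, v=v * px, valid_mask=~bad)


# ---------------------------------------------------------------------------
# FTTC


def _greens_tensor(shape: tuple[int, int], spacing: float, E: float,
                   poisson: float):
    """Fourier-space Boussinesq Green's tensor components on an FFT grid.

    Returns (Gxx, Gxy, Gyy, nonzero) with the zero-frequency entry left 0.
    """
    ny, nx = shape
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=spacing)
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX**2 + KY**2
    k = np.sqrt(k2)
    nonzero = k > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2 * (1 + poisson) / (E * k**3)
    pref[~nonzero] = 0.0
    Gxx = pref * ((1 - poisson) * k2 + poisson * KY**2)
    Gyy = pref * ((1 - poisson) * k2 + poisson * KX**2)
    Gxy = pref * (-poisson * KX * KY)
    return Gxx, Gxy, Gyy, nonzero


def forward_displacement(traction: TractionField,
                         E_gel: float | None = None,
                         poisson: float | None = None) -> DisplacementField:
    """Surface displacement produced by a traction field on the half-space.

    Evaluates ``u(k) = G(k) t(k)`` on the traction grid with periodic FFT
    boundary conditions; the zero-frequency displacement is pinned to 0.
    """
    E = E_gel if E_gel is not None else traction.E_gel
    nu = poisson if poisson is not None else traction.poisson
    tx_h = np.fft.fft2(traction.t_x)
    ty_h = np.fft.fft2(traction.t_y)
    Gxx, Gxy, Gyy, _ = _greens_tensor(traction.t_x.shape, traction.spacing,
                                      E, nu)
    u_h = Gxx * tx_h + Gxy * ty_h
    v_h = Gxy * tx_h + Gyy * ty_h
    u = np.fft.ifft2(u_h).real
    v = np.fft.ifft2(v_h).real
    return DisplacementField(grid_x=traction.grid_x, grid_y=traction.grid_y,
                             u=u, v=v,
                             valid_mask=np.ones(u.shape, dtype=bool))


def _fill_invalid(field: DisplacementField) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of flagged nodes from valid neighbors."""
    from scipy.interpolate import griddata
    u, v, ok = field.u.copy(), field.v.copy(), field.valid_mask
    if ok.all():
        return u, v
    if not ok.any():
        raise ValueError("all displacement nodes invalid")
    yy, xx = np.mgrid[0:u.shape[0], 0:u.shape[1]]
    pts = np.column_stack([yy[ok], xx[ok]])
    tgt = np.column_stack([yy[~ok], xx[~ok]])
    for comp in (u, v):
        vals = griddata(pts, comp[ok], tgt, method="linear")
        nn = griddata(pts, comp[ok], tgt, method="nearest")
        vals = np.where(np.isnan(vals), nn, vals)
        comp[~ok] = vals
    return u, v


def fttc_traction(displacement: DisplacementField, E_gel: float,
                  poisson: float = 0.5, lam: float = DEFAULT_LAMBDA,
                  window: str | None = None,
                  pad: bool = False) -> TractionField:
    """Traction field by regularized Fourier-transform traction cytometry.

    Solves ``t(k) = (G^T G + lam I)^{-1} G^T u(k)`` per nonzero wavevector
    (zeroth-order Tikhonov; ``lam = 0`` is the plain inverse) and pins the
    zero-frequency (net-force) component to 0.  ``lam`` is in (um/Pa)^2.

    ``window='hann'`` tapers the field and ``pad=True`` zero-pads to the
    next power of two before transforming (result cropped back) — useful on
    non-periodic experimental fields; both default off so that the inverse
    is the exact adjoint of :func:`forward_displacement`.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not np.all(np.isfinite(displacement.u[displacement.valid_mask])):
        raise ValueError("NaNs in displacement field: interpolate first")
    u, v = _fill_invalid(displacement)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("NaNs in displacement field: interpolate first")
    ny, nx = u.shape

    if window == "hann":
        wy = np.hanning(ny)[:, None]
        wx = np.hanning(nx)[None, :]
        u = u * wy * wx
        v = v * wy * wx
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")

    if pad:
        Ny = 1 << int(np.ceil(np.log2(ny)))
        Nx = 1 << int(np.ceil(np.log2(nx)))
        up = np.zeros((Ny, Nx))
        vp = np.zeros((Ny, Nx))
        up[:ny, :nx], vp[:ny, :nx] = u, v
        u, v = up, vp

    Gxx, Gxy, Gyy, nz = _greens_tensor(u.shape, displacement.spacing,
                                       E_gel, poisson)
    u_h = np.fft.fft2(u)
    v_h = np.fft.fft2(v)
    # normal equations of the symmetric 2x2 system per wavevector
    Axx = Gxx**2 + Gxy**2 + lam
    Ayy = Gyy**2 + Gxy**2 + lam
    Axy = Gxy * (Gxx + Gyy)
    bx = Gxx * u_h + Gxy * v_h
    by = Gxy * u_h + Gyy * v_h
    det = Axx * Ayy - Axy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        tx_h = (Ayy * bx - Axy * by) / det
        ty_h = (Axx * by - Axy * bx) / det
    tx_h[~nz] = 0.0
    ty_h[~nz] = 0.0
    tx = np.fft.ifft2(tx_h).real[:ny, :nx]
    ty = np.fft.ifft2(ty_h).real[:ny, :nx]
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(grid_x=displacement.grid_x,
                         grid_y=displacement.grid_y,
                         t_x=tx, t_y=ty, E_gel=E_gel, poisson=poisson,
                         regularization=lam)


def lcurve_lambda(displacement: DisplacementField, E_gel: float,
                  poisson: float = 0.5,
                  lambdas: np.ndarray | None = None):
    """L-curve scan for the Tikhonov weight.

    Returns ``(lambdas, residual_norms, solution_norms, corner)`` where
    ``corner`` is the lambda of maximal curvature of the log-log L-curve.
    """
    if lambdas is None:
        lambdas = np.logspace(-12, -4, 25)
    res, sol = [], []
    for lam in lambdas:
        t = fttc_traction(displacement, E_gel, poisson, lam=lam)
        u_pred = forward_displacement(t)
        res.append(np.sqrt(np.mean((u_pred.u - displacement.u)**2 +
                                   (u_pred.v - displacement.v)**2)))
        sol.append(np.sqrt(np.mean(t.t_x**2 + t.t_y**2)))
    res, sol = np.log(np.asarray(res) + 1e-300), np.log(np.asarray(sol) + 1e-300)
    x = np.log(lambdas)
    d1r, d1s = np.gradient(res, x), np.gradient(sol, x)
    d2r, d2s = np.gradient(d1r, x), np.gradient(d1s, x)
    curvature = (d1r * d2s - d1s * d2r) / (d1r**2 + d1s**2)**1.5
    corner = float(lambdas[np.nanargmax(curvature)])
    return np.asarray(lambdas), np.exp(res), np.exp(sol), corner


def summarize_traction(fields: Sequence[TractionField],
                       mask: np.ndarray | None = None,
                       mask_id: str | None = None) -> TractionSummary:
    """Median traction magnitude over space per frame, then mean over time.

    ``mask`` restricts the spatial median to nodes under the cell; the
    whole field is used when absent.
    """
    fields = list(fields)
    if len(fields) == 0:
        raise ValueError("need at least one traction field")
    medians = []
    for f in fields:
        mag = f.magnitude
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != mag.shape:
                raise ValueError("mask shape must match the traction grid")
            if not mask.any():
                raise ValueError("empty cell mask")
            mag = mag[mask]
        medians.append(float(np.median(mag)))
    medians = np.asarray(medians)
    return TractionSummary(frame_medians=medians,
                           temporal_mean=float(medians.mean()),
                           mask_id=mask_id)
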