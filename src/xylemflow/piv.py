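"""Multipass deformation cross-correlation PIV with subpixel peak fitting.

The engine estimates velocity fields from tracer-particle image pairs:

1. the image pair is interrogated on a grid of windows (initial size
   128x32 px, elongated along the flow for dynamic range) by
   zero-normalised cross-correlation;
2. the correlation peak is located to subpixel precision with the
   three-point one-dimensional Gaussian fit applied per axis;
3. vectors are validated in two stages — signal-to-noise ratio
   (primary/secondary peak, threshold 2) and a 7x7 normalised median
   test — with outliers replaced by the neighbourhood median;
4. the validated field deforms frame B toward frame A (bicubic image
   warping on a bilinearly densified predictor) and the next pass
   refines the residual on smaller windows, down to 32x8 px;
5. instantaneous fields are ensemble-averaged and longitudinal velocity
   profiles extracted at downstream stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, signal

from .synthgen import ParticleImagePair

__all__ = [
    "PivConfig",
    "CorrelationPlane",
    "VelocityField",
    "correlate_window",
    "subpixel_peak",
    "multipass_piv",
    "validate_snr",
    "validate_adaptive_median",
    "ensemble_average",
    "extract_profile",
]

_CORR_FLOOR = 1e-6


@dataclass(frozen=True)
class PivConfig:
    """Interrogation parameters.

    Window sizes are (height, width) in pixels with the long axis along
    the flow (x).  Sizes shrink geometrically from ``initial_window`` to
    ``final_window`` over ``n_passes``; defaults are 128x32 -> 64x16 ->
    32x8 with 50 % overlap.
    """

    initial_window: tuple[int, int] = (32, 128)
    final_window: tuple[int, int] = (8, 32)
    overlap: float = 0.5
    n_passes: int = 3
    snr_threshold: float = 2.0
    median_region: tuple[int, int] = (7, 7)
    median_threshold: float = 2.0
    median_eps: float = 0.1           # px, normalisation stabiliser
    dt: float = 1.0                   # interframe time, seconds
    calibration: float = 1.0          # µm per pixel

    def __post_init__(self) -> None:
        ih, iw = self.initial_window
        fh, fw = self.final_window
        if fh > ih or fw > iw:
            raise ValueError("windows must shrink from initial to final")
        if not 0.0 <= self.overlap <= 0.75:
            raise ValueError(f"overlap must lie in [0, 0.75], got {self.overlap}")
        if self.snr_threshold <= 1.0:
            raise ValueError("snr_threshold must exceed 1")
        if self.n_passes < 1:
            raise ValueError("need at least one pass")

    def window_schedule(self) -> list[tuple[int, int]]:
        """Geometric window progression, monotone non-increasing."""
        ih, iw = self.initial_window
        fh, fw = self.final_window
        if self.n_passes == 1:
            return [(fh, fw)]
        out = []
        for k in range(self.n_passes):
            f = k / (self.n_passes - 1)
            h = int(round(ih * (fh / ih) ** f))
            w = int(round(iw * (fw / iw) ** f))
            out.append((max(h, fh), max(w, fw)))
        return out


@dataclass(frozen=True)
class CorrelationPlane:
    """Normalised cross-correlation over integer lags.

    ``values[i, j]`` is the correlation at lag ``(lags_y[i], lags_x[j])``;
    a peak at lag (dy, dx) means the pattern moved by (dx, dy) px from
    window A to window B.
    """

    values: np.ndarray
    lags_y: np.ndarray
    lags_x: np.ndarray
    peak_idx: tuple[int, int]
    primary: float
    secondary: float
    valid: bool = True

    @property
    def peak_lag(self) -> tuple[int, int]:
        """(dy, dx) integer lag of the primary peak."""
        return (int(self.lags_y[self.peak_idx[0]]),
                int(self.lags_x[self.peak_idx[1]]))

    @property
    def snr(self) -> float:
        if not self.valid or self.primary <= 0:
            return 0.0
        return self.primary / max(self.secondary, 1e-12)


def correlate_window(win_a: np.ndarray, win_b: np.ndarray) -> CorrelationPlane:
    """Zero-normalised cross-correlation of two interrogation windows.

    Both windows are mean-subtracted and the plane scaled by
    ``N * sigma_a * sigma_b``; lags are restricted to the half-window
    search range.  The secondary peak is sought outside a 3x3 exclusion
    zone around the primary, giving the signal-to-noise ratio used in
    validation.  A zero-variance (flat) window yields an invalid plane.
    """
    a = np.asarray(win_a, float)
    b = np.asarray(win_b, float)
    if a.shape != b.shape:
        raise ValueError(f"window shapes differ: {a.shape} vs {b.shape}")
    h, w = a.shape
    a0 = a - a.mean()
    b0 = b - b.mean()
    sa = a0.std()
    sb = b0.std()
    sy, sx = h // 2, w // 2
    lags_y = np.arange(-sy, sy + 1)
    lags_x = np.arange(-sx, sx + 1)
    if sa < 1e-12 or sb < 1e-12:
        vals = np.zeros((lags_y.size, lags_x.size))
        return CorrelationPlane(vals, lags_y, lags_x, (sy, sx), 0.0, 0.0,
                                valid=False)

    full = signal.fftconvolve(b0, a0[::-1, ::-1], mode="full")
    plane = full[h - 1 - sy: h - 1 + sy + 1, w - 1 - sx: w - 1 + sx + 1]
    plane = plane / (a.size * sa * sb)

    iy, ix = np.unravel_index(np.argmax(plane), plane.shape)
    primary = float(plane[iy, ix])
    masked = plane.copy()
    masked[max(iy - 1, 0): iy + 2, max(ix - 1, 0): ix + 2] = -np.inf
    secondary = float(masked.max()) if np.isfinite(masked).any() else 0.0
    secondary = max(secondary, 0.0)
    return CorrelationPlane(plane, lags_y, lags_x, (int(iy), int(ix)),
                            primary, secondary, valid=primary > 0)


def _fit_1d(triple: np.ndarray) -> tuple[float, bool]:
    """Subpixel offset from three samples around a peak.

    Three-point log-Gaussian estimator (exact on a pure Gaussian peak);
    falls back to the parabolic vertex when any sample is non-positive.
    Returns (delta, used_gaussian).
    """
    rm, r0, rp = float(triple[0]), float(triple[1]), float(triple[2])
    if r0 < rm or r0 < rp:
        raise ValueError("centre sample is not a local maximum")
    if min(rm, r0, rp) > 0.0:
        lm, l0, lp = (math.log(max(v, _CORR_FLOOR)) for v in (rm, r0, rp))
        denom = 2.0 * lm + 2.0 * lp - 4.0 * l0
        if denom < 0.0:
            delta = (lm - lp) / denom
            if abs(delta) < 1.0:
                return delta, True
    denom = rm - 2.0 * r0 + rp
    if denom >= 0.0:
        return 0.0, False
    delta = 0.5 * (rm - rp) / denom
    return float(np.clip(delta, -0.999, 0.999)), False


def subpixel_peak(plane: CorrelationPlane) -> tuple[float, float]:
    """Subpixel displacement (dx, dy) from a correlation plane.

    Applies the three-point one-dimensional Gaussian fit independently
    along each axis through the primary peak.  The peak must be strictly
    interior to the searched plane.
    """
    if not plane.valid:
        raise ValueError("invalid correlation plane")
    iy, ix = plane.peak_idx
    ny, nx = plane.values.shape
    if not (0 < iy < ny - 1 and 0 < ix < nx - 1):
        raise ValueError("correlation peak on the plane border")
    dy, _ = _fit_1d(plane.values[iy - 1: iy + 2, ix])
    dx, _ = _fit_1d(plane.values[iy, ix - 1: ix + 2])
    return (plane.lags_x[ix] + dx, plane.lags_y[iy] + dy)


@dataclass
class VelocityField:
    """Velocity vectors on a regular interrogation grid.

    ``u``/``v`` are in px/frame on an (ny, nx) grid whose node centres
    are ``x``/``y`` in pixel coordinates.  ``valid`` marks vectors that
    passed validation; ``replaced`` marks vectors substituted by the
    neighbourhood median.  Calibrated velocities (µm/s) derive from the
    pixel pitch and interframe time.
    """

    x: np.ndarray             # (nx,) node centres, px
    y: np.ndarray             # (ny,) node centres, px
    u: np.ndarray             # (ny, nx) px/frame
    v: np.ndarray
    snr: np.ndarray
    valid: np.ndarray         # bool
    replaced: np.ndarray = dc_field(default=None)  # bool
    pass_index: int = 0
    dt: float = 1.0
    calibration: float = 1.0

    def __post_init__(self) -> None:
        if self.replaced is None:
            self.replaced = np.zeros_like(self.valid)

    @property
    def u_um_s(self) -> np.ndarray:
        return self.u * self.calibration / self.dt

    @property
    def v_um_s(self) -> np.ndarray:
        return self.v * self.calibration / self.dt

    def copy(self) -> "VelocityField":
        return VelocityField(
            x=self.x.copy(), y=self.y.copy(), u=self.u.copy(), v=self.v.copy(),
            snr=self.snr.copy(), valid=self.valid.copy(),
            replaced=self.replaced.copy(), pass_index=self.pass_index,
            dt=self.dt, calibration=self.calibration,
        )

    def to_table(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x_px": X.ravel(),
                "y_px": Y.ravel(),
                "u_px": self.u.ravel(),
                "v_px": self.v.ravel(),
                "u_um_s": self.u_um_s.ravel(),
                "v_um_s": self.v_um_s.ravel(),
                "snr": self.snr.ravel(),
                "valid": self.valid.ravel(),
                "replaced": self.replaced.ravel(),
            }
        )


def validate_snr(fld: VelocityField, threshold: float = 2.0) -> VelocityField:
    """Flag vectors whose correlation SNR falls below ``threshold``.

    Idempotent: already-invalid vectors stay invalid, valid ones above
    the threshold are untouched.
    """
    out = fld.copy()
    out.valid &= out.snr >= threshold
    return out


def _neighbor_stack(arr: np.ndarray, region: tuple[int, int]) -> np.ndarray:
    """(ny, nx, rh*rw) stack of each node's neighbourhood, self as NaN."""
    rh, rw = region
    py, px = rh // 2, rw // 2
    padded = np.pad(arr, ((py, py), (px, px)), constant_values=np.nan)
    win = sliding_window_view(padded, (rh, rw)).copy()
    win[:, :, py, px] = np.nan          # exclude the node itself
    return win.reshape(arr.shape + (rh * rw,))


def validate_adaptive_median(
    fld: VelocityField,
    region: tuple[int, int] = (7, 7),
    threshold: float = 2.0,
    eps: float = 0.1,
) -> VelocityField:
    """Normalised median test over a local region, with replacement.

    Each vector is compared against the median of its valid neighbours in
    the (odd-sized) region; the residual is normalised by the median of
    the neighbours' own residuals plus a stabiliser ``eps`` (px).
    Vectors whose normalised residual exceeds ``threshold`` on either
    component are flagged invalid and replaced by the neighbourhood
    median.  Detection uses the input field only, so a second application
    to a cleaned field leaves it unchanged.
    """
    rh, rw = region
    if rh % 2 == 0 or rw % 2 == 0:
        raise ValueError("median region must be odd in both dimensions")
    ny, nx = fld.u.shape
    if rh > ny * 2 + 1 or rw > nx * 2 + 1:
        raise ValueError(f"median region {region} larger than grid {(ny, nx)}")

    out = fld.copy()
    bad_in = ~fld.valid
    med, fluct = {}, {}
    for name, comp in (("u", fld.u), ("v", fld.v)):
        c = np.where(bad_in, np.nan, comp)
        stack = _neighbor_stack(c, region)
        n_valid = np.sum(np.isfinite(stack), axis=-1)
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmedian(stack, axis=-1)
            r = np.nanmedian(np.abs(stack - m[..., None]), axis=-1)
        med[name] = m
        fluct[name] = r
        med[name][n_valid < 3] = np.nan

    testable = np.isfinite(med["u"]) & np.isfinite(med["v"])
    norm_u = np.abs(fld.u - med["u"]) / (fluct["u"] + eps)
    norm_v = np.abs(fld.v - med["v"]) / (fluct["v"] + eps)
    outlier = testable & fld.valid & (
        (norm_u > threshold) | (norm_v > threshold)
    )
    # invalid vectors with a defined neighbourhood median also get replaced
    fill = (outlier | bad_in) & testable
    out.u[fill] = med["u"][fill]
    out.v[fill] = med["v"][fill]
    out.valid[outlier] = False
    out.replaced |= fill
    return out


def ensemble_average(fields: list[VelocityField]) -> VelocityField:
    """Per-node mean over valid vectors of instantaneous fields.

    A node is valid in the output only if it was valid in at least half
    of the inputs.  All fields must share the same grid.
    """
    if not fields:
        raise ValueError("need at least one field")
    f0 = fields[0]
    for f in fields[1:]:
        if not (np.array_equal(f.x, f0.x) and np.array_equal(f.y, f0.y)):
            raise ValueError("fields are on different grids")
    n = len(fields)
    u = np.stack([np.where(f.valid, f.u, np.nan) for f in fields])
    v = np.stack([np.where(f.valid, f.v, np.nan) for f in fields])
    s = np.stack([np.where(f.valid, f.snr, np.nan) for f in fields])
    count = np.sum(np.stack([f.valid for f in fields]), axis=0)
    ok = count >= max(int(math.ceil(n / 2.0)), 1)
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        um = np.nanmean(u, axis=0)
        vm = np.nanmean(v, axis=0)
        sm = np.nanmean(s, axis=0)
    um[~ok] = 0.0
    vm[~ok] = 0.0
    sm[~ok] = 0.0
    return VelocityField(x=f0.x.copy(), y=f0.y.copy(), u=um, v=vm, snr=sm,
                         valid=ok, replaced=np.zeros_like(ok),
                         pass_index=f0.pass_index, dt=f0.dt,
                         calibration=f0.calibration)


def _pass_grid(shape: tuple[int, int], win: tuple[int, int],
               overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Top-left window corners for one pass (y0 values, x0 values)."""
    H, W = shape
    wh, ww = win
    step_y = max(int(round(wh * (1.0 - overlap))), 1)
    step_x = max(int(round(ww * (1.0 - overlap))), 1)
    y0 = np.arange(0, H - wh + 1, step_y)
    x0 = np.arange(0, W - ww + 1, step_x)
    if y0.size == 0 or x0.size == 0:
        raise ValueError(f"image {shape} smaller than window {win}")
    return y0, x0


def _densify(x: np.ndarray, y: np.ndarray, u: np.ndarray, v: np.ndarray,
             shape: tuple[int, int]) -> np.ndarray:
    """Bilinear densification of a node field to pixel resolution.

    Values beyond the node hull are held at the edge value (constant
    extrapolation), which is the stable choice near walls.
    """
    H, W = shape
    px = np.arange(W) + 0.5
    py = np.arange(H) + 0.5
    xi = np.clip(np.interp(px, x, np.arange(x.size, dtype=float)), 0, x.size - 1)
    yi = np.clip(np.interp(py, y, np.arange(y.size, dtype=float)), 0, y.size - 1)
    YI, XI = np.meshgrid(yi, xi, indexing="ij")
    dense = np.empty((2, H, W))
    dense[0] = ndimage.map_coordinates(u, [YI, XI], order=1, mode="nearest")
    dense[1] = ndimage.map_coordinates(v, [YI, XI], order=1, mode="nearest")
    return dense


def multipass_piv(pair: ParticleImagePair, cfg: PivConfig | None = None) -> VelocityField:
    """Estimate the velocity field of one image pair.

    Runs the configured window schedule; after each pass the validated,
    lightly smoothed field is densified to pixel resolution and used to
    deform frame B toward frame A (bicubic warp), so later passes only
    measure the residual displacement.  Raises when the image is smaller
    than the initial window or when more than half of the final-pass
    vectors fail validation (seeding or contrast failure).
    """
    cfg = cfg or PivConfig()
    a = np.asarray(pair.frame_a, float)
    b = np.asarray(pair.frame_b, float)
    H, W = a.shape
    dense = np.zeros((2, H, W))
    fld: VelocityField | None = None

    for k, win in enumerate(cfg.window_schedule()):
        wh, ww = win
        if k == 0:
            b_work = b
        else:
            PY, PX = np.mgrid[0:H, 0:W]
            b_work = ndimage.map_coordinates(
                b, [PY + dense[1], PX + dense[0]], order=3, mode="nearest")
        y0s, x0s = _pass_grid((H, W), win, cfg.overlap)
        cx = x0s + ww / 2.0
        cy = y0s + wh / 2.0
        # predictor sampled at node centres
        pred_u = ndimage.map_coordinates(
            dense[0], np.meshgrid(cy - 0.5, cx - 0.5, indexing="ij"),
            order=1, mode="nearest")
        pred_v = ndimage.map_coordinates(
            dense[1], np.meshgrid(cy - 0.5, cx - 0.5, indexing="ij"),
            order=1, mode="nearest")

        u = np.zeros((y0s.size, x0s.size))
        v = np.zeros_like(u)
        snr = np.zeros_like(u)
        ok = np.zeros(u.shape, bool)
        for j, y0 in enumerate(y0s):
            for i, x0 in enumerate(x0s):
                plane = correlate_window(a[y0:y0 + wh, x0:x0 + ww],
                                         b_work[y0:y0 + wh, x0:x0 + ww])
                snr[j, i] = plane.snr
                if not plane.valid:
                    continue
                iy, ix = plane.peak_idx
                ny, nx = plane.values.shape
                if not (0 < iy < ny - 1 and 0 < ix < nx - 1):
                    continue
                du, dv = subpixel_peak(plane)
                u[j, i] = du
                v[j, i] = dv
                ok[j, i] = True
        u += pred_u
        v += pred_v
        u[~ok] = pred_u[~ok]
        v[~ok] = pred_v[~ok]

        fld = VelocityField(x=cx, y=cy, u=u, v=v, snr=snr, valid=ok,
                            pass_index=k, dt=cfg.dt, calibration=cfg.calibration)
        fld = validate_snr(fld, cfg.snr_threshold)
        region = (min(cfg.median_region[0], 2 * (u.shape[0] // 2) + 1),
                  min(cfg.median_region[1], 2 * (u.shape[1] // 2) + 1))
        fld = validate_adaptive_median(fld, region, cfg.median_threshold,
                                       cfg.median_eps)
        if k < cfg.n_passes - 1:
            su = ndimage.gaussian_filter(fld.u, 0.5, mode="nearest")
            sv = ndimage.gaussian_filter(fld.v, 0.5, mode="nearest")
            dense = _densify(cx, cy, su, sv, (H, W))

    assert fld is not None
    if np.mean(~fld.valid & ~fld.replaced) > 0.5:
        raise RuntimeError(
            "more than 50% of final-pass vectors are invalid — "
            "insufficient seeding or contrast")
    return fld


def extract_profile(
    fld: VelocityField,
    station_x_um: float,
    normalization_U0: float | None = None,
) -> pd.DataFrame:
    """Transverse profile of the longitudinal component at one station.

    The station (µm downstream) is converted to pixels with the field's
    calibration and the profile linearly interpolated between the two
    bracketing grid columns.  Returns a table of ``y_um``, ``u_um_s``
    and, when a reference mean velocity ``normalization_U0`` (µm/s) is
    given, the normalised ``U_over_U0``.
    """
    x_px = station_x_um / fld.calibration
    if not (fld.x[0] <= x_px <= fld.x[-1]):
        raise ValueError(
            f"station {station_x_um} µm ({x_px:.1f} px) outside field extent "
            f"[{fld.x[0]:.1f}, {fld.x[-1]:.1f}] px")
    i = int(np.searchsorted(fld.x, x_px, side="right") - 1)
    i = min(i, fld.x.size - 2)
    t = (x_px - fld.x[i]) / (fld.x[i + 1] - fld.x[i])
    u_col = (1 - t) * fld.u_um_s[:, i] + t * fld.u_um_s[:, i + 1]
    out = pd.DataFrame({"y_um": fld.y * fld.calibration, "u_um_s": u_col})
    if normalization_U0 is not None:
        out["U_over_U0"] = u_col / normalization_U0
    return out
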