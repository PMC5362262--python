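"""Astigmatism-based 3D single-molecule localization.

A cylindrical lens in the detection path makes the PSF elliptical away from
focus: the Gaussian widths along the two camera axes defocus in opposite
directions, so the axial position of a molecule is encoded in the
ellipticity of its image.  This module detects candidate spots, fits each
with a pixel-integrated elliptical Gaussian, and inverts the fitted widths
(wx, wy) through an analytic defocus calibration

    wx(z) = w0 * sqrt(1 + ((z - c)/d)^2)
    wy(z) = w0 * sqrt(1 + ((z + c)/d)^2)

to obtain z.  The inversion minimizes the distance in sqrt-width space (the
established astigmatism convention); plain width distance is available as
an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .errors import ParameterError
from .synthgen import FrameStack, integrated_gaussian
from .tables import LocalizationTable

__all__ = [
    "AstigCalibration",
    "SpotFit",
    "detect_spots",
    "fit_spot",
    "estimate_z",
    "localize_stack",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AstigCalibration:
    """Analytic wx(z)/wy(z) defocus curves of the astigmatic PSF.

    ``w0_nm`` is the common focal width (Gaussian SD), ``offset_c_nm`` the
    +/- focal-plane offset of the two lateral axes introduced by the
    cylindrical lens, and ``depth_d_nm`` the defocus depth scale.  The two
    curves are mirror images: wx(z) = wy(-z), and wx(0) = wy(0).
    """

    w0_nm: float = 150.0
    offset_c_nm: float = 150.0
    depth_d_nm: float = 400.0
    valid_z_range_nm: tuple[float, float] = (-400.0, 400.0)

    def __post_init__(self) -> None:
        if self.w0_nm <= 0 or self.depth_d_nm <= 0:
            raise ParameterError("w0_nm and depth_d_nm must be > 0")
        lo, hi = self.valid_z_range_nm
        if not lo < hi:
            raise ParameterError("valid_z_range_nm must be a nonempty interval")

    def wx(self, z_nm):
        z = np.asarray(z_nm, float)
        return self.w0_nm * np.sqrt(1.0 + ((z - self.offset_c_nm) / self.depth_d_nm) ** 2)

    def wy(self, z_nm):
        z = np.asarray(z_nm, float)
        return self.w0_nm * np.sqrt(1.0 + ((z + self.offset_c_nm) / self.depth_d_nm) ** 2)


@dataclass
class SpotFit:
    """Result of an elliptical-Gaussian fit to one candidate spot."""

    x_nm: float
    y_nm: float
    wx_nm: float
    wy_nm: float
    photons: float
    background: float
    z_nm: float = math.nan
    residual: float = math.nan
    converged: bool = True
    z_in_range: bool = True


def detect_spots(
    frame: np.ndarray,
    threshold_k: float = 5.0,
    roi_px: int = 11,
    smooth_sigma_px: float = 1.0,
) -> list[tuple[int, int]]:
    """Local maxima exceeding background + k * noise SD, >= roi apart.

    Maxima are evaluated on a Gaussian-smoothed copy of the frame
    (``smooth_sigma_px``); smoothing suppresses the heavy discrete-Poisson
    tail of raw pixels so the k-sigma threshold behaves like a Gaussian
    tail bound.  Background is the smoothed-frame median; the noise scale
    is the larger of the analytic shot-noise SD of the smoothed field,
    sqrt(background * sum(w^2)) with w the discrete smoothing kernel
    (stable, exact for photon-counting frames), and the robust (MAD) SD
    (guards against excess noise).  Candidates are returned ordered by
    (row, column); plateau and proximity ties are resolved greedily in
    that order, so the output is deterministic.
    """
    frame = np.asarray(frame, float)
    if frame.size == 0:
        raise ParameterError("frame is empty")
    if smooth_sigma_px > 0:
        sm = ndimage.gaussian_filter(frame, smooth_sigma_px)
        half = int(math.ceil(4 * smooth_sigma_px))
        impulse = np.zeros((2 * half + 1, 2 * half + 1))
        impulse[half, half] = 1.0
        sum_w2 = float((ndimage.gaussian_filter(impulse, smooth_sigma_px) ** 2).sum())
    else:
        sm = frame
        sum_w2 = 1.0
    bg = float(np.median(sm))
    mad = float(np.median(np.abs(sm - bg)))
    sd_shot = math.sqrt(max(bg, 1.0) * sum_w2)
    sd = max(1.4826 * mad, sd_shot)
    threshold = bg + threshold_k * sd

    footprint = np.ones((roi_px, roi_px), bool)
    is_max = sm == ndimage.maximum_filter(sm, footprint=footprint, mode="nearest")
    # exclude a border margin: reflection padding inflates edge variance and
    # spots there cannot be fit with a full ROI
    margin = max(int(math.ceil(2 * smooth_sigma_px)), roi_px // 4)
    if min(frame.shape) > 2 * margin:
        border = np.zeros(frame.shape, bool)
        border[margin:-margin, margin:-margin] = True
        is_max &= border
    cand = np.argwhere(is_max & (sm > threshold))
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    kept: list[tuple[int, int]] = []
    for r, c in cand:
        if all(max(abs(r - kr), abs(c - kc)) >= roi_px for kr, kc in kept):
            kept.append((int(r), int(c)))
    return kept


def _spot_model(params, shape, pixel_size_nm):
    x, y, wx, wy, photons, bg = params
    return integrated_gaussian(shape, x, y, wx, wy, photons, bg, pixel_size_nm)


def fit_spot(
    roi: np.ndarray,
    init_center_px: tuple[float, float] | None = None,
    pixel_size_nm: float = 100.0,
) -> SpotFit:
    """Least-squares pixel-integrated elliptical Gaussian fit of one spot.

    Returns a :class:`SpotFit` with ``converged=False`` (never raises) for
    degenerate patches such as a constant ROI.
    """
    roi = np.asarray(roi, float)
    rows, cols = roi.shape
    a = pixel_size_nm
    bg0 = float(np.median(roi))
    signal = roi - bg0
    total = float(signal.sum())
    if np.ptp(roi) == 0 or total <= 0:
        return SpotFit(math.nan, math.nan, math.nan, math.nan, 0.0, bg0, converged=False)

    if init_center_px is None:
        r0, c0 = np.unravel_index(int(np.argmax(roi)), roi.shape)
    else:
        r0, c0 = init_center_px
    x0 = (c0 + 0.5) * a
    y0 = (r0 + 0.5) * a

    def residuals(p):
        return (_spot_model(p, roi.shape, a) - roi).ravel()

    p0 = np.array([x0, y0, 1.5 * a, 1.5 * a, max(total, 1.0), bg0])
    bounds = (
        [0.0, 0.0, 0.2 * a, 0.2 * a, 0.0, 0.0],
        [cols * a, rows * a, cols * a, rows * a, np.inf, np.inf],
    )
    try:
        sol = optimize.least_squares(residuals, p0, bounds=bounds, xtol=1e-10, ftol=1e-10)
    except Exception:  # pragma: no cover - scipy failures are treated as non-convergence
        return SpotFit(x0, y0, math.nan, math.nan, total, bg0, converged=False)
    x, y, wx, wy, photons, bg = sol.x
    resid = float(np.sqrt(np.mean(sol.fun**2)))
    return SpotFit(x, y, wx, wy, photons, bg, residual=resid, converged=bool(sol.success))


def estimate_z(
    wx_nm: float,
    wy_nm: float,
    cal: AstigCalibration,
    *,
    metric: str = "sqrt",
    grid_step_nm: float = 2.0,
) -> tuple[float, bool]:
    """Invert fitted widths to axial position via the calibration curves.

    Minimizes (sqrt(wx) - sqrt(wx_cal(z)))^2 + (sqrt(wy) - sqrt(wy_cal(z)))^2
    (or the plain-width analogue with ``metric="plain"``) on a fine grid
    over the valid range, then refines with a bounded scalar minimization.
    Returns ``(z_nm, in_range)``; ``in_range`` is False when the optimum
    sits at a boundary of the valid range or is ambiguous (two equal
    minima, resolved toward smaller \\|z\\|).
    """
    if not (np.isfinite(wx_nm) and np.isfinite(wy_nm)) or wx_nm <= 0 or wy_nm <= 0:
        raise ParameterError("widths must be finite and positive")
    if metric not in ("sqrt", "plain"):
        raise ParameterError(f"unknown z metric {metric!r}")

    lo, hi = cal.valid_z_range_nm
    zgrid = np.arange(lo, hi + grid_step_nm, grid_step_nm)

    def cost(z):
        cwx, cwy = cal.wx(z), cal.wy(z)
        if metric == "sqrt":
            return (math.sqrt(wx_nm) - np.sqrt(cwx)) ** 2 + (math.sqrt(wy_nm) - np.sqrt(cwy)) ** 2
        return (wx_nm - cwx) ** 2 + (wy_nm - cwy) ** 2

    d = cost(zgrid)
    near_min = np.nonzero(d <= d.min() * (1 + 1e-9) + 1e-30)[0]
    # split near-minimal grid indices into contiguous basins; ambiguity =
    # more than one basin (possible outside the monotonic range)
    basins = np.split(near_min, np.nonzero(np.diff(near_min) > 1)[0] + 1)
    ambiguous = len(basins) > 1
    idx = min((int(b[np.argmin(np.abs(zgrid[b]))]) for b in basins), key=lambda i: abs(zgrid[i]))

    z_lo = max(lo, zgrid[idx] - grid_step_nm)
    z_hi = min(hi, zgrid[idx] + grid_step_nm)
    res = optimize.minimize_scalar(cost, bounds=(z_lo, z_hi), method="bounded",
                                   options={"xatol": 1e-4})
    z = float(res.x)
    at_boundary = (z - lo) < grid_step_nm or (hi - z) < grid_step_nm
    return z, not (ambiguous or at_boundary)


def localize_stack(
    stack: FrameStack,
    cal: AstigCalibration,
    threshold_k: float = 5.0,
    roi_px: int = 11,
    *,
    z_metric: str = "sqrt",
) -> LocalizationTable:
    """Detect, fit and z-estimate every spot in a frame stack.

    Per-frame failures (no candidates, non-converged fits, out-of-range z)
    are logged and skipped; the stack is never aborted.  The output table
    has ``source="fitted"``.
    """
    rows_out: list[tuple] = []
    half = roi_px // 2
    for i, frame in enumerate(stack.frames):
        ox, oy = stack.origins_nm[i]
        for r, c in detect_spots(frame, threshold_k, roi_px):
            r0 = int(np.clip(r - half, 0, frame.shape[0] - roi_px))
            c0 = int(np.clip(c - half, 0, frame.shape[1] - roi_px))
            roi = frame[r0 : r0 + roi_px, c0 : c0 + roi_px]
            fit = fit_spot(roi, (r - r0, c - c0), stack.pixel_size_nm)
            if not fit.converged:
                log.debug("frame %d: fit did not converge at (%d, %d)", i, r, c)
                continue
            z, in_range = estimate_z(fit.wx_nm, fit.wy_nm, cal, metric=z_metric)
            if not in_range:
                log.debug("frame %d: z out of calibration range at (%d, %d)", i, r, c)
                continue
            x_abs = ox + c0 * stack.pixel_size_nm + fit.x_nm
            y_abs = oy + r0 * stack.pixel_size_nm + fit.y_nm
            rows_out.append((i, x_abs, y_abs, z, fit.photons, fit.wx_nm, fit.wy_nm))

    arr = np.array(rows_out, float).reshape(-1, 7)
    return LocalizationTable.from_arrays(
        frame=arr[:, 0].astype(int),
        xyz=arr[:, 1:4],
        photons=arr[:, 4],
        sigma_x_nm=arr[:, 5],
        sigma_y_nm=arr[:, 6],
        source="fitted",
    )
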