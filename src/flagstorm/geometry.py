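"""Flagellar axis fitting and cylindrical projection.

The flagellum is an elongated structure, so its longitudinal axis is the
dominant principal direction of the localization cloud.  Localizations are
then expressed in cylindrical coordinates (s, r, theta) with s measured
from the annulus (the midpiece/principal-piece junction, the longitudinal
origin) toward the tip, r the distance from the axis, and theta a
right-handed angle about the axis.  Membrane ("surface-localized")
molecules are selected by a radial band around the modal radius.

Annulus identification is caller-supplied — either an explicit coordinate
or the ``"min-s"`` end of the cloud — because on real data the annulus is
located morphologically, which cannot be automated from localizations
alone.  The theta reference direction defaults to the first principal
direction orthogonal to the axis but can be overridden; for four-fold
symmetric clouds the cross-sectional covariance is nearly isotropic and
the automatic reference is arbitrary (only relative angles are then
meaningful).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AxisFitError, ParameterError
from .tables import LocalizationTable

__all__ = [
    "AxisModel",
    "fit_axis",
    "to_cylindrical",
    "select_surface",
]

TWO_PI = 2.0 * np.pi


@dataclass
class AxisModel:
    """Longitudinal axis with the annulus as s = 0.

    Straight by default; ``control_points`` (ordered along s, nm) switch on
    polyline projection for gently curved flagella, with the cross-
    sectional frame parallel-transported along the polyline.
    """

    direction: np.ndarray  # unit 3-vector, s increases annulus -> tip
    annulus_point: np.ndarray  # 3-vector, projects to s = 0
    reference_direction: np.ndarray | None = None  # theta = 0 direction
    control_points: np.ndarray | None = None  # (m, 3) polyline, optional

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        n = np.linalg.norm(self.direction)
        if not n > 0:
            raise ParameterError("axis direction must be nonzero")
        self.direction = self.direction / n
        self.annulus_point = np.asarray(self.annulus_point, float)
        if self.reference_direction is not None:
            e1 = np.asarray(self.reference_direction, float)
            e1 = e1 - (e1 @ self.direction) * self.direction
            n1 = np.linalg.norm(e1)
            if not n1 > 0:
                raise ParameterError("reference_direction is parallel to the axis")
            self.reference_direction = e1 / n1

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Right-handed perpendicular basis (e1, e2): e1 x e2 = direction."""
        if self.reference_direction is not None:
            e1 = self.reference_direction
        else:
            helper = np.zeros(3)
            helper[int(np.argmin(np.abs(self.direction)))] = 1.0
            e1 = np.cross(helper, self.direction)
            e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.direction, e1)
        return e1, e2


def fit_axis(
    table: LocalizationTable | np.ndarray,
    *,
    annulus: str | np.ndarray = "min-s",
    min_anisotropy: float = 2.0,
    curved: bool = False,
    window_nm: float = 1000.0,
) -> AxisModel:
    """Fit the longitudinal axis as the dominant principal direction.

    Parameters
    ----------
    table
        Localization table or (n, 3) coordinate array; n >= 10 required.
    annulus
        ``"min-s"`` / ``"max-s"`` to pin s = 0 at one extreme of the cloud,
        or an explicit 3-vector that is projected onto the axis.  The axis
        direction is oriented so the data lie at s >= 0 (annulus -> tip).
    min_anisotropy
        Minimum ratio of the first to second singular value; below it the
        cloud is considered isotropic and an :class:`AxisFitError` is
        raised with the measured ratio.
    curved
        Refine with a windowed-centroid polyline (window ``window_nm``).
    """
    pts = table.xyz if isinstance(table, LocalizationTable) else np.asarray(table, float)
    if len(pts) < 10:
        raise ParameterError(f"axis fit requires >= 10 localizations, got {len(pts)}")
    centre = pts.mean(axis=0)
    centred = pts - centre
    _, sv, vt = np.linalg.svd(centred, full_matrices=False)
    if sv[1] > 0 and sv[0] / sv[1] < min_anisotropy:
        raise AxisFitError(
            f"point cloud too isotropic for axis fitting: "
            f"anisotropy {sv[0] / max(sv[1], 1e-300):.2f} < {min_anisotropy}"
        )
    direction = vt[0]
    s = centred @ direction

    if isinstance(annulus, str):
        if annulus == "min-s":
            origin = centre + s.min() * direction
        elif annulus == "max-s":
            origin = centre + s.max() * direction
            direction = -direction
        else:
            raise ParameterError(f"annulus must be 'min-s', 'max-s' or a point, got {annulus!r}")
    else:
        origin = np.asarray(annulus, float)
        # orient so the bulk of the data sits at s >= 0
        if np.median((pts - origin) @ direction) < 0:
            direction = -direction

    reference = vt[1] - (vt[1] @ direction) * direction
    reference /= np.linalg.norm(reference)
    axis = AxisModel(direction=direction, annulus_point=origin, reference_direction=reference)

    if curved:
        s_all = (pts - axis.annulus_point) @ axis.direction
        nbins = max(2, int(math.ceil((s_all.max() - s_all.min()) / window_nm)))
        edges = np.linspace(s_all.min(), s_all.max(), nbins + 1)
        idx = np.clip(np.digitize(s_all, edges) - 1, 0, nbins - 1)
        ctrl = np.array([pts[idx == b].mean(axis=0) for b in range(nbins) if np.any(idx == b)])
        if len(ctrl) >= 2:
            # window centroids sit half a window inside the data span; extend
            # the end segments so the polyline covers the whole flagellum
            t0 = ctrl[0] - ctrl[1]
            t1 = ctrl[-1] - ctrl[-2]
            head = ctrl[0] + t0 / np.linalg.norm(t0) * window_nm
            tail = ctrl[-1] + t1 / np.linalg.norm(t1) * window_nm
            axis.control_points = np.vstack([head, ctrl, tail])
    return axis


def _polyline_frames(ctrl: np.ndarray, e1_start: np.ndarray):
    """Per-segment (tangent, n1, n2) with n1 parallel-transported along."""
    tangents = np.diff(ctrl, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n1 = e1_start - (e1_start @ tangents[0]) * tangents[0]
    n1 /= np.linalg.norm(n1)
    frames = []
    prev_t = tangents[0]
    for t in tangents:
        # minimal rotation taking prev_t to t (Rodrigues), applied to n1
        c = float(prev_t @ t)
        axis = np.cross(prev_t, t)
        s = np.linalg.norm(axis)
        if s > 1e-12:
            k = axis / s
            n1 = n1 * c + np.cross(k, n1) * s + k * (k @ n1) * (1.0 - c)
            n1 -= (n1 @ t) * t
            n1 /= np.linalg.norm(n1)
        frames.append((t, n1.copy(), np.cross(t, n1)))
        prev_t = t
    return frames


def _project_polyline(pts: np.ndarray, axis: AxisModel):
    ctrl = axis.control_points
    e1, _ = axis.frame()
    frames = _polyline_frames(ctrl, e1)
    seg_vec = np.diff(ctrl, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # annulus offset: arc-length position of the annulus point on the polyline
    s0 = _polyline_s(axis.annulus_point[None, :], ctrl, seg_vec, seg_len, cum)[0]

    s_out = np.empty(len(pts))
    r_out = np.empty(len(pts))
    th_out = np.empty(len(pts))
    for i, p in enumerate(pts):
        t = ((p - ctrl[:-1]) * seg_vec).sum(axis=1) / seg_len**2
        t = np.clip(t, 0.0, 1.0)
        foot = ctrl[:-1] + t[:, None] * seg_vec
        d2 = ((p - foot) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        s_out[i] = cum[j] + t[j] * seg_len[j] - s0
        tang, n1, n2 = frames[j]
        v = p - foot[j]
        a, b = float(v @ n1), float(v @ n2)
        r_out[i] = math.hypot(a, b)
        th_out[i] = math.atan2(b, a) % TWO_PI if r_out[i] > 0 else 0.0
    return s_out, r_out, th_out


def _polyline_s(pts, ctrl, seg_vec, seg_len, cum):
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        t = ((p - ctrl[:-1]) * seg_vec).sum(axis=1) / seg_len**2
        t = np.clip(t, 0.0, 1.0)
        foot = ctrl[:-1] + t[:, None] * seg_vec
        j = int(np.argmin(((p - foot) ** 2).sum(axis=1)))
        out[i] = cum[j] + t[j] * seg_len[j]
    return out


def to_cylindrical(table: LocalizationTable, axis: AxisModel) -> pd.DataFrame:
    """Project localizations to (s, r, theta) about the fitted axis.

    Returns a DataFrame with columns ``s_nm, r_nm, theta_rad`` plus the
    source table's columns passed through.  theta is in [0, 2*pi),
    measured right-handedly from the reference direction; a point exactly
    on the axis gets theta = 0 by convention.
    """
    pts = table.xyz
    if axis.control_points is not None and len(axis.control_points) >= 2:
        s, r, theta = _project_polyline(pts, axis)
    else:
        rel = pts - axis.annulus_point
        s = rel @ axis.direction
        e1, e2 = axis.frame()
        a = rel @ e1
        b = rel @ e2
        r = np.hypot(a, b)
        theta = np.where(r > 0, np.arctan2(b, a) % TWO_PI, 0.0)
    out = pd.DataFrame({"s_nm": s, "r_nm": r, "theta_rad": theta})
    return pd.concat([out, table.df.reset_index(drop=True)], axis=1)


def select_surface(
    cyl: pd.DataFrame,
    band: tuple[float, float] | None = None,
    *,
    n_sigma: float = 3.0,
    hist_bin_nm: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cylindrical table into surface (membrane) and rejected points.

    With ``band=None`` the band is [r_mode - n_sigma*s_r, r_mode +
    n_sigma*s_r], where r_mode is the mode of a ``hist_bin_nm``-binned
    radial histogram and s_r a robust (MAD) spread of radii within 100 nm
    of the mode.  Counts are conserved: the two outputs partition the
    input.
    """
    if len(cyl) == 0:
        raise ParameterError("surface selection requires a nonempty table")
    r = cyl["r_nm"].to_numpy()
    if band is None:
        edges = np.arange(0.0, r.max() + hist_bin_nm, hist_bin_nm)
        if len(edges) < 2:
            edges = np.array([0.0, hist_bin_nm])
        counts, edges = np.histogram(r, bins=edges)
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        near = r[np.abs(r - mode) <= 100.0]
        sigma_r = 1.4826 * np.median(np.abs(near - np.median(near)))
        if sigma_r == 0:
            sigma_r = hist_bin_nm / 2.0
        band = (mode - n_sigma * sigma_r, mode + n_sigma * sigma_r)
    lo, hi = band
    mask = (r >= lo) & (r <= hi)
    if not mask.any():
        warnings.warn("surface band selected no localizations", stacklevel=2)
    return cyl[mask].reset_index(drop=True), cyl[~mask].reset_index(drop=True)
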