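"""Synthetic flagellar STORM ground truth and localization-noise model.

The sperm flagellum principal piece is modelled as a cylinder of ~300 nm
radius whose membrane carries four longitudinal protein stripes at the
quadrant diagonals ("racing stripes").  Two regimes are generated:

* continuous stripes (wild-type-like organization), and
* stripes periodically fragmented by emitter-free gaps with a period of
  ~0.8 µm (the CatSperζ-null-like regime, in which the quadrilateral
  arrangement persists but each stripe is interrupted at roughly the
  fibrous-sheath rib spacing).

:func:`sample_emitters` draws true fluorophore positions on the cylinder
surface; :func:`corrupt_to_localizations` turns them into a noisy
localization table (repeated blinks, Gaussian localization error, uniform
cytosolic background); :func:`render_frames` produces raw astigmatic camera
frames from which the localization stage can re-derive the table.

Randomness is split into independent streams per purpose (emitters, gap
phases, blink replication, localization noise, background, photon counts,
shot noise) so that toggling one ingredient never perturbs the draws of
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, RangeError
from .tables import LocalizationTable

__all__ = [
    "FlagellumModel",
    "GroundTruth",
    "CameraModel",
    "FrameStack",
    "sample_emitters",
    "corrupt_to_localizations",
    "render_frames",
    "DEFAULT_STRIPE_ANGLES",
]

#: Quadrant-diagonal stripe angles (rad): the four-fold arrangement.
DEFAULT_STRIPE_ANGLES = (np.pi / 4, 3 * np.pi / 4, 5 * np.pi / 4, 7 * np.pi / 4)

# Stream indices for per-purpose random generators.
_S_EMITTERS = 0
_S_GAPS = 1
_S_REPLICATION = 2
_S_NOISE = 3
_S_BACKGROUND = 4
_S_PHOTONS = 5
_S_SHOT = 6


def _stream(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(purpose,)))


def _perp_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed (e1, e2) basis perpendicular to ``axis``.

    e1 x e2 = axis, so theta measured from e1 toward e2 follows the
    right-hand rule about the axis.
    """
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


@dataclass(frozen=True)
class FlagellumModel:
    """Parametric striped-cylinder flagellum.

    Lengths in nm, angles in rad, densities as stated per field.
    ``gap_period_nm == 0`` selects the continuous-stripe (wild-type-like)
    regime; a positive period fragments each stripe with a jittered
    square-wave mask of duty ``gap_duty`` (fraction of each period that is
    emitter-free).  ``curvature_per_nm`` optionally bends the centreline
    into a circular arc so axis fitting is exercised on non-straight data.
    """

    length_nm: float = 10_000.0
    radius_nm: float = 300.0
    axis_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    annulus_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stripe_angles_rad: tuple[float, ...] = DEFAULT_STRIPE_ANGLES
    stripe_angular_halfwidth_rad: float = math.radians(15.0)
    gap_period_nm: float = 0.0
    gap_duty: float = 0.5
    gap_phase_jitter_sd_nm: float = 0.0
    emitter_density_per_nm: float = 0.05
    background_density_per_um3: float = 5.0
    sigma_xy_nm: float = 10.0
    sigma_z_nm: float = 25.0
    mean_locs_per_emitter: float = 3.0
    mean_photons: float = 5000.0
    curvature_per_nm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.length_nm > 0:
            raise ParameterError("length_nm must be > 0")
        if not self.radius_nm > 0:
            raise ParameterError("radius_nm must be > 0")
        if not (0 <= self.gap_duty < 1):
            raise ParameterError("gap_duty must lie in [0, 1)")
        if self.gap_period_nm < 0:
            raise ParameterError("gap_period_nm must be >= 0")
        if self.gap_period_nm > 0 and not self.length_nm > self.gap_period_nm:
            raise ParameterError("length_nm must exceed gap_period_nm when gaps are enabled")
        ang = np.mod(np.asarray(self.stripe_angles_rad, float), 2 * np.pi)
        if len(ang) != len(np.unique(np.round(ang, 12))):
            raise ParameterError("stripe angles must be pairwise distinct modulo 2*pi")
        for name in (
            "emitter_density_per_nm",
            "background_density_per_um3",
            "sigma_xy_nm",
            "sigma_z_nm",
            "gap_phase_jitter_sd_nm",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.mean_locs_per_emitter > 0:
            raise ParameterError("mean_locs_per_emitter must be > 0")
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-9:
            raise ParameterError("axis_direction must be a unit vector")

    # -- geometry helpers ---------------------------------------------------

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.axis_direction, float)

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.annulus_point, float)

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference perpendicular basis (e1, e2) defining theta = 0."""
        return _perp_frame(self.axis)

    def surface_points(self, s: np.ndarray, theta: np.ndarray, r: np.ndarray | None = None) -> np.ndarray:
        """Map (s, theta[, r]) to Cartesian nm coordinates.

        For a straight model the centreline is ``origin + s*axis``; with
        ``curvature_per_nm`` > 0 it is a circular arc of radius 1/kappa in
        the (axis, e1) plane, with the cross-sectional frame rotating along.
        """
        s = np.asarray(s, float)
        theta = np.asarray(theta, float)
        rr = np.full_like(s, self.radius_nm) if r is None else np.asarray(r, float)
        e1, e2 = self.frame()
        kappa = self.curvature_per_nm
        if kappa == 0.0:
            centre = self.origin[None, :] + s[:, None] * self.axis[None, :]
            n1 = np.broadcast_to(e1, centre.shape)
            n2 = np.broadcast_to(e2, centre.shape)
        else:
            rc = 1.0 / kappa
            phi = s * kappa
            centre = (
                self.origin[None, :]
                + rc * np.sin(phi)[:, None] * self.axis[None, :]
                + rc * (1.0 - np.cos(phi))[:, None] * e1[None, :]
            )
            # normal rotates with the arc; binormal e2 is constant
            n1 = -np.sin(phi)[:, None] * self.axis[None, :] + np.cos(phi)[:, None] * e1[None, :]
            n2 = np.broadcast_to(e2, centre.shape)
        return centre + rr[:, None] * (np.cos(theta)[:, None] * n1 + np.sin(theta)[:, None] * n2)


@dataclass
class GroundTruth:
    """True emitter positions on the flagellar surface plus gap bookkeeping."""

    emitter_xyz: np.ndarray  # (n, 3) nm
    emitter_stripe_id: np.ndarray  # (n,) int index into stripe_angles_rad
    emitter_s_nm: np.ndarray  # (n,) longitudinal coordinate
    emitter_theta_rad: np.ndarray  # (n,) angle in the model frame
    gap_intervals: np.ndarray  # (m, 2) half-open [start, end) in s
    axis_direction: np.ndarray
    annulus_point: np.ndarray
    true_period_nm: float

    def __len__(self) -> int:
        return len(self.emitter_xyz)


def _draw_gap_intervals(model: FlagellumModel, rng: np.random.Generator) -> np.ndarray:
    """Jittered square-wave gap mask [kP + j, kP + duty*P + j') clipped to [0, L]."""
    if model.gap_period_nm <= 0 or model.gap_duty <= 0:
        return np.empty((0, 2))
    period = model.gap_period_nm
    n_periods = int(math.ceil(model.length_nm / period)) + 1
    starts = np.arange(n_periods) * period
    ends = starts + model.gap_duty * period
    if model.gap_phase_jitter_sd_nm > 0:
        starts = starts + rng.normal(0.0, model.gap_phase_jitter_sd_nm, n_periods)
        ends = ends + rng.normal(0.0, model.gap_phase_jitter_sd_nm, n_periods)
    lo = np.clip(starts, 0.0, model.length_nm)
    hi = np.clip(np.maximum(ends, starts), 0.0, model.length_nm)
    keep = hi > lo
    return np.column_stack([lo[keep], hi[keep]])


def _in_intervals(s: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    if intervals.size == 0:
        return np.zeros(len(s), bool)
    inside = np.zeros(len(s), bool)
    for lo, hi in intervals:
        inside |= (s >= lo) & (s < hi)
    return inside


def sample_emitters(model: FlagellumModel) -> GroundTruth:
    """Draw true emitter positions on the striped cylinder surface.

    Per stripe, emitter count is Poisson(density * length) with s uniform
    on [0, L] and angle uniform within the stripe half-width; positions in
    the gap mask are rejected.  Emitters lie exactly on the cylinder
    surface.  Fully reproducible from ``model.seed``.
    """
    model.validate()
    rng = _stream(model.seed, _S_EMITTERS)
    gaps = _draw_gap_intervals(model, _stream(model.seed, _S_GAPS))

    s_all, th_all, sid_all = [], [], []
    hw = model.stripe_angular_halfwidth_rad
    for i, ang in enumerate(model.stripe_angles_rad):
        n = rng.poisson(model.emitter_density_per_nm * model.length_nm)
        s = rng.uniform(0.0, model.length_nm, n)
        theta = np.mod(ang + rng.uniform(-hw, hw, n), 2 * np.pi)
        keep = ~_in_intervals(s, gaps)
        s_all.append(s[keep])
        th_all.append(theta[keep])
        sid_all.append(np.full(int(keep.sum()), i, int))

    s = np.concatenate(s_all) if s_all else np.empty(0)
    theta = np.concatenate(th_all) if th_all else np.empty(0)
    sid = np.concatenate(sid_all) if sid_all else np.empty(0, int)
    xyz = model.surface_points(s, theta) if len(s) else np.empty((0, 3))
    return GroundTruth(
        emitter_xyz=xyz,
        emitter_stripe_id=sid,
        emitter_s_nm=s,
        emitter_theta_rad=theta,
        gap_intervals=gaps,
        axis_direction=model.axis,
        annulus_point=model.origin,
        true_period_nm=model.gap_period_nm,
    )


def corrupt_to_localizations(
    truth: GroundTruth,
    model: FlagellumModel,
    *,
    fixed_locs_per_emitter: bool = False,
) -> LocalizationTable:
    """Replicate, displace and contaminate emitters into a localization table.

    Each emitter yields k ~ Poisson(mean_locs_per_emitter) localizations
    (or exactly round(mean) when ``fixed_locs_per_emitter``), displaced by
    independent N(0, sigma_xy^2) in x and y and N(0, sigma_z^2) in z —
    the optical axis is the laboratory z regardless of flagellum
    orientation.  Uniform background localizations fill the bounding
    cylinder at ``background_density_per_um3``.
    """
    model.validate()
    rng_rep = _stream(model.seed, _S_REPLICATION)
    rng_noise = _stream(model.seed, _S_NOISE)
    rng_bg = _stream(model.seed, _S_BACKGROUND)
    rng_phot = _stream(model.seed, _S_PHOTONS)

    n_em = len(truth)
    if fixed_locs_per_emitter:
        k = np.full(n_em, max(1, round(model.mean_locs_per_emitter)), int)
    else:
        k = rng_rep.poisson(model.mean_locs_per_emitter, n_em)
    pts = np.repeat(truth.emitter_xyz, k, axis=0) if n_em else np.empty((0, 3))
    n_loc = len(pts)
    if n_loc and (model.sigma_xy_nm > 0 or model.sigma_z_nm > 0):
        noise = rng_noise.normal(0.0, 1.0, (n_loc, 3))
        noise[:, 0] *= model.sigma_xy_nm
        noise[:, 1] *= model.sigma_xy_nm
        noise[:, 2] *= model.sigma_z_nm
        pts = pts + noise

    # uniform background in the cylinder of the model radius over [0, L]
    vol_um3 = math.pi * (model.radius_nm / 1000.0) ** 2 * (model.length_nm / 1000.0)
    n_bg = rng_bg.poisson(model.background_density_per_um3 * vol_um3)
    if n_bg:
        s_bg = rng_bg.uniform(0.0, model.length_nm, n_bg)
        r_bg = model.radius_nm * np.sqrt(rng_bg.uniform(0.0, 1.0, n_bg))
        th_bg = rng_bg.uniform(0.0, 2 * np.pi, n_bg)
        bg = model.surface_points(s_bg, th_bg, r_bg)
        pts = np.vstack([pts, bg]) if n_loc else bg

    n = len(pts)
    photons = rng_phot.gamma(2.0, model.mean_photons / 2.0, n) if n else np.empty(0)
    return LocalizationTable.from_arrays(
        frame=np.arange(n),
        xyz=pts,
        photons=photons,
        source="synthetic",
        seed=model.seed,
    )


# ---------------------------------------------------------------------------
# raw-frame rendering (forward model of astigmatic imaging)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Idealized camera for rendering isolated astigmatic spots."""

    pixel_size_nm: float = 100.0
    frame_shape: tuple[int, int] = (32, 32)  # (rows, cols) = (y, x)
    photons_per_emitter: float = 5000.0
    background_photons_per_px: float = 10.0
    poisson_noise: bool = True


@dataclass
class FrameStack:
    """Rendered frames plus the nm origin of pixel (0, 0) in each frame.

    One emitter is rendered per frame so spots are isolated; ``origins_nm``
    lets absolute coordinates be reconstructed from in-frame fits.
    """

    frames: np.ndarray  # (n, rows, cols) expected photon counts or noisy draws
    origins_nm: np.ndarray  # (n, 2): (x0, y0) of the corner of pixel (0, 0)
    pixel_size_nm: float

    def __len__(self) -> int:
        return len(self.frames)


def integrated_gaussian(
    shape: tuple[int, int],
    x_nm: float,
    y_nm: float,
    wx_nm: float,
    wy_nm: float,
    photons: float,
    background: float,
    pixel_size_nm: float,
) -> np.ndarray:
    """Expected photon counts of an elliptical Gaussian integrated over pixels.

    (x_nm, y_nm) is measured from the corner of pixel (0, 0); wx, wy are
    Gaussian SDs along the camera x (columns) and y (rows) axes.
    """
    from scipy.special import erf

    rows, cols = shape
    a = pixel_size_nm
    ex = 0.5 * (
        erf((np.arange(cols + 1) * a - x_nm) / (math.sqrt(2.0) * wx_nm))
    )
    ey = 0.5 * (
        erf((np.arange(rows + 1) * a - y_nm) / (math.sqrt(2.0) * wy_nm))
    )
    fx = np.diff(ex)
    fy = np.diff(ey)
    return photons * np.outer(fy, fx) + background


def render_frames(
    truth: GroundTruth,
    calibration,
    camera: CameraModel = CameraModel(),
    *,
    seed: int = 0,
) -> FrameStack:
    """Render each emitter as one astigmatic spot in its own frame.

    Spot widths follow the calibration defocus curves wx(z), wy(z); the
    emitter is placed near the frame centre with its true sub-pixel offset
    preserved, and the frame origin recorded so localization can recover
    absolute coordinates.  Shot noise is Poisson when the camera says so.
    """
    z = truth.emitter_xyz[:, 2] if len(truth) else np.empty(0)
    lo, hi = calibration.valid_z_range_nm
    bad = np.nonzero((z < lo) | (z > hi))[0]
    if bad.size:
        raise RangeError(f"emitters outside calibration z range [{lo}, {hi}] nm: indices {bad.tolist()}")

    rng = _stream(seed, _S_SHOT)
    rows, cols = camera.frame_shape
    a = camera.pixel_size_nm
    frames = np.empty((len(truth), rows, cols))
    origins = np.empty((len(truth), 2))
    for i, (x, y, zz) in enumerate(truth.emitter_xyz):
        x0 = math.floor(x / a) * a - (cols // 2) * a
        y0 = math.floor(y / a) * a - (rows // 2) * a
        wx = calibration.wx(zz)
        wy = calibration.wy(zz)
        frames[i] = integrated_gaussian(
            (rows, cols), x - x0, y - y0, wx, wy,
            camera.photons_per_emitter, camera.background_photons_per_px, a,
        )
        origins[i] = (x0, y0)
    if camera.poisson_noise:
        frames = rng.poisson(frames).astype(float)
    return FrameStack(frames=frames, origins_nm=origins, pixel_size_nm=a)
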