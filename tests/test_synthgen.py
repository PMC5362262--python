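"""Generator invariants: surface placement, gap masks, noise moments."""

import numpy as np
import pytest
from scipy import stats

from flagstorm import (
    CameraModel,
    FlagellumModel,
    ParameterError,
    corrupt_to_localizations,
    render_frames,
    sample_emitters,
)
from flagstorm.synthgen import _draw_gap_intervals, _stream


def dist_to_axis(truth):
    rel = truth.emitter_xyz - truth.annulus_point
    along = rel @ truth.axis_direction
    return np.linalg.norm(rel - along[:, None] * truth.axis_direction[None, :], axis=1)


class TestSampleEmitters:
    def test_zero_density_gives_empty_cloud(self):
        truth = sample_emitters(FlagellumModel(emitter_density_per_nm=0.0, seed=1))
        assert len(truth) == 0

    def test_emitters_lie_exactly_on_cylinder_surface(self, null_model):
        truth = sample_emitters(null_model)
        np.testing.assert_allclose(dist_to_axis(truth), null_model.radius_nm, rtol=0, atol=1e-9)

    def test_total_count_matches_poisson_mean_over_seeds(self):
        # 4 stripes x 0.05/nm x 10000 nm => mean 2000 per realization
        counts = [
            len(sample_emitters(FlagellumModel(gap_period_nm=0.0, seed=s)))
            for s in range(100)
        ]
        mean = np.mean(counts)
        se = np.sqrt(2000 / 100)
        assert abs(mean - 2000) < 4 * se

    def test_stripe_occupancy_within_poisson_bounds(self, wt_model):
        truth = sample_emitters(wt_model)
        lam = wt_model.emitter_density_per_nm * wt_model.length_nm
        for sid in range(4):
            n = int((truth.emitter_stripe_id == sid).sum())
            assert abs(n - lam) < 4 * np.sqrt(lam)

    def test_no_emitters_inside_gaps_at_zero_jitter(self, null_model):
        truth = sample_emitters(null_model)
        phase = np.mod(truth.emitter_s_nm, 800.0)
        assert not np.any(phase < 400.0)
        assert len(truth.gap_intervals) > 0

    def test_gap_leakage_grows_with_jitter(self):
        leaks = []
        for jitter in (0.0, 40.0, 120.0):
            frac = []
            for s in range(15):
                m = FlagellumModel(gap_period_nm=800.0, gap_phase_jitter_sd_nm=jitter, seed=s)
                truth = sample_emitters(m)
                phase = np.mod(truth.emitter_s_nm, 800.0)
                frac.append(np.mean(phase < 400.0))
            leaks.append(np.mean(frac))
        assert leaks[0] == 0.0
        assert leaks[0] < leaks[1] < leaks[2]

    def test_determinism_bit_for_bit(self, null_model):
        a = sample_emitters(null_model)
        b = sample_emitters(null_model)
        np.testing.assert_array_equal(a.emitter_xyz, b.emitter_xyz)
        np.testing.assert_array_equal(a.emitter_stripe_id, b.emitter_stripe_id)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(radius_nm=-1.0),
            dict(gap_duty=1.0),
            dict(gap_period_nm=800.0, length_nm=500.0),
            dict(stripe_angles_rad=(0.1, 0.1 + 2 * np.pi)),
            dict(emitter_density_per_nm=-0.1),
        ],
    )
    def test_invalid_models_raise_parameter_error(self, bad):
        with pytest.raises(ParameterError):
            sample_emitters(FlagellumModel(**bad))


class TestCorrupt:
    def test_noiseless_identity(self):
        m = FlagellumModel(sigma_xy_nm=0.0, sigma_z_nm=0.0, mean_locs_per_emitter=1.0,
                           background_density_per_um3=0.0, seed=3)
        truth = sample_emitters(m)
        table = corrupt_to_localizations(truth, m, fixed_locs_per_emitter=True)
        np.testing.assert_array_equal(table.xyz, truth.emitter_xyz)
        assert table.source == "synthetic"

    def test_lateral_noise_moment(self):
        m = FlagellumModel(sigma_xy_nm=10.0, sigma_z_nm=0.0, mean_locs_per_emitter=6.0,
                           background_density_per_um3=0.0, seed=4)
        truth = sample_emitters(m)
        table = corrupt_to_localizations(truth, m, fixed_locs_per_emitter=True)
        rep = np.repeat(truth.emitter_xyz, 6, axis=0)
        disp = table.xyz - rep
        assert len(disp) >= 10_000
        for axis in (0, 1):
            assert 9.0 <= disp[:, axis].std() <= 11.0
        np.testing.assert_allclose(disp[:, 2], 0.0, atol=1e-12)

    def test_background_only_theta_uniform(self):
        m = FlagellumModel(emitter_density_per_nm=0.0, background_density_per_um3=3000.0, seed=5)
        truth = sample_emitters(m)
        table = corrupt_to_localizations(truth, m)
        e1, e2 = m.frame()
        rel = table.xyz - m.origin
        theta = np.mod(np.arctan2(rel @ e2, rel @ e1), 2 * np.pi)
        counts, _ = np.histogram(theta, bins=12)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_toggling_background_preserves_emitter_noise_draws(self):
        m0 = FlagellumModel(background_density_per_um3=0.0, seed=6)
        m1 = FlagellumModel(background_density_per_um3=5.0, seed=6)
        truth = sample_emitters(m0)
        t0 = corrupt_to_localizations(truth, m0)
        t1 = corrupt_to_localizations(truth, m1)
        np.testing.assert_array_equal(t0.xyz, t1.xyz[: len(t0)])

    def test_determinism_bit_for_bit(self, null_model):
        truth = sample_emitters(null_model)
        a = corrupt_to_localizations(truth, null_model)
        b = corrupt_to_localizations(truth, null_model)
        assert a.df.equals(b.df)


class TestRenderFrames:
    def test_single_focal_emitter_symmetric_widths(self, calibration):
        from flagstorm.loc3d import fit_spot

        m = FlagellumModel(emitter_density_per_nm=0.0, seed=0)
        truth = sample_emitters(m)
        truth.emitter_xyz = np.array([[1650.0, 1234.0, 0.0]])
        cam = CameraModel(poisson_noise=False)
        stack = render_frames(truth, calibration, cam)
        fit = fit_spot(stack.frames[0], pixel_size_nm=cam.pixel_size_nm)
        assert fit.converged
        assert fit.wx_nm == pytest.approx(calibration.w0_nm * np.sqrt(1 + (150 / 400) ** 2), rel=1e-3)
        assert fit.wx_nm == pytest.approx(fit.wy_nm, rel=1e-3)

    def test_defocused_width_ratio_matches_calibration(self, calibration):
        from flagstorm.loc3d import fit_spot

        truth = sample_emitters(FlagellumModel(emitter_density_per_nm=0.0, seed=0))
        truth.emitter_xyz = np.array([[800.0, 800.0, 200.0]])
        stack = render_frames(truth, calibration, CameraModel(poisson_noise=False))
        fit = fit_spot(stack.frames[0])
        expected = calibration.wx(200.0) / calibration.wy(200.0)
        assert fit.wx_nm / fit.wy_nm == pytest.approx(expected, rel=0.02)

    def test_empty_scene_is_pure_background(self, calibration):
        truth = sample_emitters(FlagellumModel(emitter_density_per_nm=0.0,
                                               background_density_per_um3=0.0, seed=0))
        cam = CameraModel(background_photons_per_px=20.0)
        stack = render_frames(truth, calibration, cam, seed=1)
        assert stack.frames.shape[0] == 0

    def test_out_of_range_emitter_raises(self, calibration):
        from flagstorm import RangeError

        truth = sample_emitters(FlagellumModel(emitter_density_per_nm=0.0, seed=0))
        truth.emitter_xyz = np.array([[0.0, 0.0, 900.0]])
        with pytest.raises(RangeError):
            render_frames(truth, calibration, CameraModel())


def test_gap_intervals_tile_the_length():
    m = FlagellumModel(gap_period_nm=800.0, gap_duty=0.25, seed=2)
    gaps = _draw_gap_intervals(m, _stream(m.seed, 1))
    widths = gaps[:, 1] - gaps[:, 0]
    interior = widths[(gaps[:, 0] > 0) & (gaps[:, 1] < m.length_nm)]
    np.testing.assert_allclose(interior, 200.0, atol=1e-9)
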