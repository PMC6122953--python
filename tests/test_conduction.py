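"""Activation mapping, surface fitting, velocity field and CV summaries."""

import numpy as np
import pytest

from perinexus.conduction import (
    ActivationMap,
    ActivationMapper,
    ConductionVelocityEstimator,
    activation_delay,
    apd,
    compute_activation_map,
    cv_summary,
    fit_parabolic_surface,
    velocity_field,
)
from perinexus.synth import OpticalMovieConfig, gen_optical_movie
from perinexus.synth.optical import ap_template


def _true_map(truth):
    return np.asarray(truth.records["activation_ms"])


def _make_map(times, pixel_size_mm=0.1, valid=None, pacing=None):
    valid = np.ones_like(times, dtype=bool) if valid is None else valid
    if pacing is None:
        masked = np.where(valid, times, np.inf)
        pacing = tuple(int(v) for v in np.unravel_index(np.argmin(masked), times.shape))
    return ActivationMap(
        times_ms=times, valid=valid, pixel_size_mm=pixel_size_mm,
        frame_rate=1000.0, pacing_pixel=pacing,
    )


# ---------------------------------------------------------------------------
# activation detection
# ---------------------------------------------------------------------------


class TestActivationMap:
    def test_noiseless_movie_recovers_truth_within_a_frame(self):
        cfg = OpticalMovieConfig(grid=(40, 40), noise_sigma=0.0)
        movie, truth = gen_optical_movie(cfg, seed=0)
        amap = compute_activation_map(movie, cfg.frame_rate)
        assert amap.valid.all()
        err = np.abs(amap.times_ms - _true_map(truth))
        assert err.max() <= 1000.0 / cfg.frame_rate  # one frame

    def test_noisy_movie_recovers_95_percent_within_2_ms(self):
        cfg = OpticalMovieConfig(grid=(60, 60), noise_sigma=0.05)
        movie, truth = gen_optical_movie(cfg, seed=3)
        amap = compute_activation_map(movie, cfg.frame_rate)
        err = np.abs(amap.times_ms - _true_map(truth))[amap.valid]
        assert (err <= 2.0).mean() >= 0.95

    def test_constant_pixel_is_masked(self):
        cfg = OpticalMovieConfig(grid=(20, 20), noise_sigma=0.0)
        movie, _ = gen_optical_movie(cfg, seed=0)
        movie[:, 5, 5] = 0.42  # dead pixel
        amap = compute_activation_map(movie, cfg.frame_rate)
        assert not amap.valid[5, 5]
        assert amap.valid.sum() == 20 * 20 - 1

    def test_all_flat_movie_raises(self):
        with pytest.raises(ValueError, match="no activations"):
            compute_activation_map(np.zeros((50, 8, 8)), 1000.0)

    def test_pacing_pixel_is_earliest_activation(self):
        cfg = OpticalMovieConfig(grid=(30, 30), noise_sigma=0.0, pacing_site=(7, 21))
        movie, _ = gen_optical_movie(cfg, seed=0)
        amap = compute_activation_map(movie, cfg.frame_rate)
        assert amap.pacing_pixel == (7, 21)


# ---------------------------------------------------------------------------
# parabolic surface
# ---------------------------------------------------------------------------


class TestParabolicSurface:
    def test_exact_quadratic_recovered_to_1e9(self):
        coeffs = np.array([0.7, -0.3, 0.15, 2.0, -1.0, 5.0])
        ny = nx = 25
        x = (np.arange(nx) + 0.5) * 0.1
        y = (np.arange(ny) + 0.5) * 0.1
        xx, yy = np.meshgrid(x, y)
        a, b, c, d, e, f = coeffs
        t = a * xx**2 + b * yy**2 + c * xx * yy + d * xx + e * yy + f
        surf = fit_parabolic_surface(_make_map(t, pacing=(0, 0)))
        np.testing.assert_allclose(surf.coefficients, coeffs, rtol=1e-9, atol=1e-9)
        assert surf.rms_ms < 1e-9

    def test_planar_wave_gives_pure_linear_surface(self):
        c = 0.5  # mm/ms
        ny = nx = 20
        xx, yy = np.meshgrid((np.arange(nx) + 0.5) * 0.1, (np.arange(ny) + 0.5) * 0.1)
        surf = fit_parabolic_surface(_make_map(xx / c, pacing=(0, 0)))
        np.testing.assert_allclose(surf.coefficients[:3], 0.0, atol=1e-9)
        assert surf.coefficients[3] == pytest.approx(1 / c, rel=1e-9)
        np.testing.assert_allclose(surf.coefficients[4], 0.0, atol=1e-9)

    def test_too_few_valid_pixels_raise(self):
        t = np.zeros((3, 3))
        valid = np.zeros((3, 3), dtype=bool)
        valid[0, :2] = True
        with pytest.raises(ValueError, match=">= 6 valid"):
            fit_parabolic_surface(_make_map(t, valid=valid, pacing=(0, 0)))

    def test_collinear_pixels_are_rank_deficient(self):
        t = np.arange(64, dtype=float).reshape(8, 8)
        valid = np.zeros((8, 8), dtype=bool)
        valid[3, :] = True  # a single row: x varies, y fixed
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_parabolic_surface(_make_map(t, valid=valid, pacing=(3, 0)))

    def test_noisy_coefficients_converge_with_grid_size(self):
        """OLS coefficient error shrinks roughly like 1/sqrt(N pixels)."""
        coeffs = np.array([0.5, 0.2, 0.1, 1.0, 0.5, 30.0])
        errors = {}
        for n in (20, 80):
            errs = []
            for seed in range(12):
                rng = np.random.default_rng(seed)
                xx, yy = np.meshgrid(
                    (np.arange(n) + 0.5) * 0.1, (np.arange(n) + 0.5) * 0.1
                )
                a, b, c, d, e, f = coeffs
                t = a * xx**2 + b * yy**2 + c * xx * yy + d * xx + e * yy + f
                t = t + rng.normal(0, 0.5, t.shape)
                surf = fit_parabolic_surface(_make_map(t, pacing=(0, 0)))
                errs.append(np.abs(surf.coefficients[3] - d))
            errors[n] = np.mean(errs)
        # 16x more pixels -> ~4x smaller error; allow generous slack
        assert errors[80] < errors[20] / 2


# ---------------------------------------------------------------------------
# velocity field and CV summary
# ---------------------------------------------------------------------------


class TestVelocity:
    def test_planar_wave_speed_everywhere(self):
        c = 0.5  # mm/ms = 50 cm/s
        ny = nx = 30
        xx, _ = np.meshgrid((np.arange(nx) + 0.5) * 0.1, (np.arange(ny) + 0.5) * 0.1)
        amap = _make_map(xx / c, pacing=(15, 0))
        surf = fit_parabolic_surface(amap)
        field = velocity_field(amap, surface=surf, mode="global", radial_mask=False,
                               pacing_exclusion_px=0.0)
        sp = field.speed_cm_s[field.valid]
        np.testing.assert_allclose(sp, 50.0, rtol=1e-9)
        assert np.allclose(field.vy_cm_s[field.valid], 0.0, atol=1e-9)

    def test_local_mode_matches_global_on_quadratic(self):
        ny = nx = 30
        xx, yy = np.meshgrid((np.arange(nx) + 0.5) * 0.1, (np.arange(ny) + 0.5) * 0.1)
        t = 0.3 * xx**2 + 0.5 * yy**2 + 1.2 * xx + 0.4 * yy + 2.0
        amap = _make_map(t, pacing=(0, 0))
        f_loc = velocity_field(amap, mode="local", radial_mask=False, pacing_exclusion_px=0.0)
        f_glob = velocity_field(amap, mode="global", radial_mask=False, pacing_exclusion_px=0.0)
        m = f_loc.valid & f_glob.valid
        np.testing.assert_allclose(f_loc.vx_cm_s[m], f_glob.vx_cm_s[m], rtol=1e-6)
        np.testing.assert_allclose(f_loc.vy_cm_s[m], f_glob.vy_cm_s[m], rtol=1e-6)

    def test_isotropic_circular_wave_speed(self):
        cfg = OpticalMovieConfig(grid=(60, 60), cv_l_cm_s=30.0, cv_t_cm_s=30.0, noise_sigma=0.0)
        _, truth = gen_optical_movie(cfg, seed=0)
        amap = _make_map(_true_map(truth))
        field = velocity_field(amap)
        sp = field.speed_cm_s[field.valid]
        assert np.median(np.abs(sp - 30.0) / 30.0) < 0.02

    def test_elliptical_axis_speeds_within_5_percent(self):
        cfg = OpticalMovieConfig(noise_sigma=0.0)
        _, truth = gen_optical_movie(cfg, seed=0)
        field = velocity_field(_make_map(_true_map(truth)))
        summ = cv_summary(field)
        assert summ.cv_l_cm_s == pytest.approx(50.0, rel=0.05)
        assert summ.cv_t_cm_s == pytest.approx(20.0, rel=0.05)


class TestCVSummary:
    def test_full_recovery_on_synthetic_movie(self):
        cfg = OpticalMovieConfig()  # CV_L 50, CV_T 20, axis 30 deg, 5% noise
        movie, _ = gen_optical_movie(cfg, seed=1)
        est = ConductionVelocityEstimator().fit(movie)
        assert est.cv_l_cm_s_ == pytest.approx(50.0, rel=0.05)
        assert est.cv_t_cm_s_ == pytest.approx(20.0, rel=0.05)
        assert est.anisotropy_ratio_ == pytest.approx(2.5, rel=0.05)
        assert abs(est.fast_axis_deg_ - 30.0) <= 2.0
        assert est.summary_.anisotropy_ratio == est.cv_l_cm_s_ / est.cv_t_cm_s_

    def test_isotropic_wave_has_unit_anisotropy(self):
        cfg = OpticalMovieConfig(cv_l_cm_s=30.0, cv_t_cm_s=30.0)
        movie, _ = gen_optical_movie(cfg, seed=2)
        est = ConductionVelocityEstimator().fit(movie)
        assert est.anisotropy_ratio_ == pytest.approx(1.0, abs=0.05)

    def test_rotating_the_movie_rotates_the_fast_axis(self):
        cfg = OpticalMovieConfig()
        movie, _ = gen_optical_movie(cfg, seed=4)
        est0 = ConductionVelocityEstimator().fit(movie)
        # rot90 maps (row, col) -> (n-1-col, row): angles rotate by -90 deg
        rotated = np.rot90(movie, k=1, axes=(1, 2))
        est1 = ConductionVelocityEstimator().fit(rotated)
        delta = (est0.fast_axis_deg_ - est1.fast_axis_deg_) % 180.0
        assert min(abs(delta - 90.0), abs(delta + 90.0 - 180.0)) <= 2.0
        assert est1.anisotropy_ratio_ == pytest.approx(est0.anisotropy_ratio_, rel=0.02)

    def test_amplitude_scaling_leaves_summary_unchanged(self):
        cfg = OpticalMovieConfig(grid=(60, 60), noise_sigma=0.0)
        movie, _ = gen_optical_movie(cfg, seed=5)
        est0 = ConductionVelocityEstimator().fit(movie)
        est1 = ConductionVelocityEstimator().fit(movie * 7.3)
        assert est1.cv_l_cm_s_ == pytest.approx(est0.cv_l_cm_s_, rel=1e-9)
        assert est1.anisotropy_ratio_ == pytest.approx(est0.anisotropy_ratio_, rel=1e-9)

    def test_doubling_frame_rate_changes_cv_by_under_2_percent(self):
        base = OpticalMovieConfig(grid=(60, 60), noise_sigma=0.0)
        fast = OpticalMovieConfig(grid=(60, 60), noise_sigma=0.0, frame_rate=2000.0)
        m0, _ = gen_optical_movie(base, seed=0)
        m1, _ = gen_optical_movie(fast, seed=0)
        e0 = ConductionVelocityEstimator(frame_rate=1000.0).fit(m0)
        e1 = ConductionVelocityEstimator(frame_rate=2000.0).fit(m1)
        assert e1.cv_l_cm_s_ == pytest.approx(e0.cv_l_cm_s_, rel=0.02)
        assert e1.cv_t_cm_s_ == pytest.approx(e0.cv_t_cm_s_, rel=0.02)

    def test_empty_field_raises(self):
        from perinexus.conduction import VelocityField

        empty = VelocityField(
            vx_cm_s=np.zeros((5, 5)), vy_cm_s=np.zeros((5, 5)),
            valid=np.zeros((5, 5), dtype=bool),
        )
        with pytest.raises(ValueError, match="empty velocity field"):
            cv_summary(empty)


# ---------------------------------------------------------------------------
# APD and activation delay
# ---------------------------------------------------------------------------


class TestApd:
    def test_square_pulse_apd_is_pulse_width(self):
        trace = np.zeros(200)
        trace[50:130] = 1.0  # 80 ms pulse at 1 kHz
        for level in (0.3, 0.5, 0.8):
            assert apd(trace, 1000.0, level) == pytest.approx(80.0, abs=1.5)

    def test_template_apd_matches_analytic_crossing(self):
        cfg = OpticalMovieConfig(noise_sigma=0.0)
        t = np.arange(0.0, 250.0, 1.0)
        trace = ap_template(t, 50.0, cfg)
        level = 0.8
        # closed form: repolarization exp(-(dt - plateau)/tau) crosses
        # (1 - level) at dt = plateau + tau * ln(1/(1 - level))
        expected = cfg.plateau_ms + cfg.repol_tau_ms * np.log(1 / (1 - level))
        assert apd(trace, 1000.0, level) == pytest.approx(expected, abs=2.0)

    def test_zero_level_errors_by_default_and_full_mode_returns_span(self):
        trace = np.zeros(100)
        trace[20:60] = 1.0
        with pytest.raises(ValueError):
            apd(trace, 1000.0, 0.0)
        full = apd(trace, 1000.0, 0.0, on_zero_level="full")
        assert full == pytest.approx(100.0 - 20.0, abs=2.0)

    def test_no_repolarization_raises(self):
        trace = np.concatenate([np.zeros(20), np.ones(50)])
        with pytest.raises(ValueError, match="no repolarization"):
            apd(trace, 1000.0, 0.8)


class TestActivationDelay:
    def test_planar_wave_delay_is_distance_over_speed(self):
        c = 0.5  # mm/ms
        xx, _ = np.meshgrid((np.arange(30) + 0.5) * 0.1, (np.arange(30) + 0.5) * 0.1)
        amap = _make_map(xx / c, pacing=(15, 0))
        # 10 pixels = 1 mm apart along propagation
        assert activation_delay(amap, (15, 5), (15, 15)) == pytest.approx(1.0 / c)

    def test_same_site_delay_is_zero(self):
        amap = _make_map(np.random.default_rng(0).uniform(0, 10, (8, 8)))
        assert activation_delay(amap, (4, 4), (4, 4)) == 0.0

    def test_synthetic_elliptical_delay_matches_truth(self):
        cfg = OpticalMovieConfig(grid=(60, 60), noise_sigma=0.0)
        movie, truth = gen_optical_movie(cfg, seed=0)
        amap = compute_activation_map(movie, cfg.frame_rate)
        t_true = _true_map(truth)
        a, b = (10, 10), (45, 50)
        expected = t_true[b] - t_true[a]
        assert activation_delay(amap, a, b) == pytest.approx(expected, abs=1.0)

    def test_invalid_site_raises(self):
        amap = _make_map(np.zeros((5, 5)), valid=np.eye(5, dtype=bool) > 0)
        with pytest.raises(ValueError, match="no valid activation"):
            activation_delay(amap, (0, 0), (0, 1))
        with pytest.raises(ValueError, match="outside the map"):
            activation_delay(amap, (0, 0), (9, 9))
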