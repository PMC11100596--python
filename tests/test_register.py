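"""Phase-only correlation, least-squares matching and drift correction."""

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from protrusion_smt import register, simulate
from protrusion_smt.benchmarks import fiducial_drift_config
from protrusion_smt.config import DriftModel, SimConfig
from protrusion_smt.io import Movie


def brute_force_circular_argmax(a, b):
    """Oracle: integer shift maximizing the circular cross-correlation."""
    h, w = a.shape
    best, best_shift = -np.inf, (0, 0)
    a0 = a - a.mean()
    b0 = b - b.mean()
    for dy in range(h):
        for dx in range(w):
            score = float(np.sum(a0 * np.roll(b0, (-dy, -dx), axis=(0, 1))))
            if score > best:
                best, best_shift = score, (dx, dy)
    wrap = lambda v, n: v - n if v > n // 2 else v
    return wrap(best_shift[0], w), wrap(best_shift[1], h)


class TestPhaseCorrelation:
    def test_identity(self):
        # broadband image: every spectral bin carries signal, so the
        # phase correlation of an image with itself peaks at ~1
        image = np.random.default_rng(0).random((64, 64))
        dx, dy, peak = register.phase_correlation_shift(image, image)
        assert dx == pytest.approx(0.0, abs=1e-9)
        assert dy == pytest.approx(0.0, abs=1e-9)
        assert peak > 0.9

    @pytest.mark.parametrize("shift", [(3, -2), (-5, 7), (0, 1)])
    def test_integer_shift_matches_brute_force(self, shift):
        rng = np.random.default_rng(0)
        a = rng.random((32, 32))
        b = np.roll(a, (shift[1], shift[0]), axis=(0, 1))
        dx, dy, _ = register.phase_correlation_shift(a, b, subpixel_mode="none")
        assert (dx, dy) == shift
        assert brute_force_circular_argmax(a, b) == shift

    def test_subpixel_shift_recovered(self, textured_image, fourier_shift):
        b = fourier_shift(textured_image, 1.25, -0.5)
        dx, dy, _ = register.phase_correlation_shift(
            textured_image, b, subpixel_mode="upsample"
        )
        assert abs(dx - 1.25) < 0.05
        assert abs(dy + 0.5) < 0.05

    def test_agrees_with_skimage(self, textured_image, fourier_shift):
        b = fourier_shift(textured_image, 0.8, -1.4)
        dx, dy, _ = register.phase_correlation_shift(
            textured_image, b, subpixel_mode="upsample"
        )
        (sk_dy, sk_dx), _, _ = phase_cross_correlation(
            textured_image, b, upsample_factor=100, normalization="phase"
        )
        assert dx == pytest.approx(-sk_dx, abs=0.05)
        assert dy == pytest.approx(-sk_dy, abs=0.05)

    def test_antisymmetry(self, textured_image, fourier_shift):
        b = fourier_shift(textured_image, 0.6, -1.1)
        f = register.phase_correlation_shift(textured_image, b)
        g = register.phase_correlation_shift(b, textured_image)
        assert abs(f[0] + g[0]) < 0.02
        assert abs(f[1] + g[1]) < 0.02

    def test_constant_image_rejected(self):
        flat = np.ones((32, 32))
        with pytest.raises(register.DegenerateImageError):
            register.phase_correlation_shift(flat, flat)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            register.phase_correlation_shift(np.zeros((32, 32)), np.zeros((16, 32)))


class TestLSMRefinement:
    def test_fixed_point_on_exact_shift(self, textured_image, fourier_shift):
        b = fourier_shift(textured_image, 1.0, -2.0)
        dx, dy, converged = register.refine_shift_lsm(
            textured_image, b, (1.0, -2.0)
        )
        assert converged
        assert dx == pytest.approx(1.0, abs=0.02)
        assert dy == pytest.approx(-2.0, abs=0.02)

    def test_pure_gain_case(self, textured_image):
        b = 2.0 * textured_image
        dx, dy, converged = register.refine_shift_lsm(textured_image, b, (0.0, 0.0))
        assert converged
        assert abs(dx) < 0.05 and abs(dy) < 0.05

    def test_refinement_beats_poc_alone(self, fourier_shift):
        """Paired comparison on noisy subpixel shifts (SNR ~10)."""
        rng = np.random.default_rng(1)
        from scipy import ndimage

        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            base = ndimage.gaussian_filter(rng.random((48, 48)), 1.5)
            true = rng.uniform(-1.5, 1.5, size=2)
            a = base + base.std() / 10 * rng.standard_normal(base.shape)
            b = fourier_shift(base, *true) + base.std() / 10 * rng.standard_normal(
                base.shape
            )
            px, py, _ = register.phase_correlation_shift(a, b)
            lx, ly, _ = register.refine_shift_lsm(a, b, (px, py))
            err_poc = np.hypot(px - true[0], py - true[1])
            err_lsm = np.hypot(lx - true[0], ly - true[1])
            if err_lsm <= err_poc:
                wins += 1
        assert wins >= 0.7 * n_rep

    def test_flat_image_returns_unconverged(self):
        flat = np.ones((32, 32))
        dx, dy, converged = register.refine_shift_lsm(flat, flat, (0.3, 0.1))
        assert not converged
        assert (dx, dy) == (0.3, 0.1)


class TestEstimateDrift:
    def test_null_drift(self):
        # SNR ~20 scene: estimated trace should be zero to within 0.05 px
        cfg = SimConfig.from_dict(
            {
                **fiducial_drift_config(3).to_dict(),
                "drift_model": {},
                "quantal_brightness": 4000.0,
            }
        )
        movie = simulate.render_movie(simulate.simulate_tracks(cfg), cfg)
        trace = register.estimate_drift(movie)
        assert np.max(np.hypot(trace.dx_px, trace.dy_px)) < 0.05

    def test_linear_drift_recovered(self):
        cfg = fiducial_drift_config(
            4, linear_px_per_frame=(0.05, 0.03), sine_amp_px=(0.0, 0.0)
        )
        movie = simulate.render_movie(simulate.simulate_tracks(cfg), cfg)
        true = cfg.drift_model.displacement_nm(np.arange(cfg.n_frames)) / cfg.pixel_size
        trace = register.estimate_drift(movie)
        err = np.hypot(trace.dx_px - true[:, 0], trace.dy_px - true[:, 1])
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_sequential_mode_tracks_sinusoid(self):
        # brighter scene: chaining adjacent shifts accumulates per-pair
        # noise as a random walk, so this mode needs good SNR
        cfg = SimConfig.from_dict(
            {
                **fiducial_drift_config(
                    5, linear_px_per_frame=(0.0, 0.0), sine_amp_px=(2.0, 0.0)
                ).to_dict(),
                "quantal_brightness": 2000.0,
            }
        )
        movie = simulate.render_movie(simulate.simulate_tracks(cfg), cfg)
        true = cfg.drift_model.displacement_nm(np.arange(cfg.n_frames)) / cfg.pixel_size
        trace = register.estimate_drift(movie, reference_mode="sequential")
        err = np.hypot(trace.dx_px - true[:, 0], trace.dy_px - true[:, 1])
        assert np.sqrt(np.mean(err**2)) < 0.15

    def test_too_few_frames_rejected(self):
        movie = Movie(np.zeros((1, 32, 32)), 162.5, 1.0)
        with pytest.raises(ValueError, match="2 frames"):
            register.estimate_drift(movie)

    def test_sparse_scene_yields_zero_trace(self):
        # a scene whose only content is moving molecules cannot be
        # registered; the estimator must refuse rather than guess
        cfg = SimConfig(n_molecules=3, n_frames=30, rng_seed=12)
        movie = simulate.render_movie(simulate.simulate_tracks(cfg), cfg)
        trace = register.estimate_drift(movie)
        if trace.low_confidence[1:].mean() > 0.5:
            assert np.all(trace.dx_px == 0)
            assert np.all(trace.dy_px == 0)


class TestApplyCorrection:
    def test_zero_trace_is_identity(self):
        rng = np.random.default_rng(0)
        movie = Movie(rng.random((4, 32, 32)), 162.5, 1.0)
        trace = register.DriftTrace(np.zeros(4), np.zeros(4), np.ones(4))
        out = register.apply_drift_correction(movie, trace)
        np.testing.assert_array_equal(out.data, movie.data)

    def test_integer_shift_nearest_is_exact(self):
        rng = np.random.default_rng(1)
        movie = Movie(rng.random((2, 32, 32)), 162.5, 1.0)
        trace = register.DriftTrace(
            np.array([0.0, 3.0]), np.array([0.0, -2.0]), np.ones(2)
        )
        out = register.apply_drift_correction(movie, trace, interpolation="nearest")
        # interior pixels are a pure index shift
        np.testing.assert_array_equal(
            out.data[1][5:25, 5:25], movie.data[1][3:23, 8:28]
        )
        assert np.isnan(out.data[1][:, -3:]).all()

    def test_length_mismatch_rejected(self):
        movie = Movie(np.zeros((3, 32, 32)), 162.5, 1.0)
        trace = register.DriftTrace(np.zeros(2), np.zeros(2), np.ones(2))
        with pytest.raises(ValueError, match="length"):
            register.apply_drift_correction(movie, trace)

    def test_closed_loop_roundtrip(self):
        cfg = fiducial_drift_config(6)
        movie = simulate.render_movie(simulate.simulate_tracks(cfg), cfg)
        trace = register.estimate_drift(movie)
        corrected = register.apply_drift_correction(movie, trace)
        residual = register.estimate_drift(corrected)
        assert np.max(np.hypot(residual.dx_px, residual.dy_px)) < 0.05

    def test_trace_csv_roundtrip(self, tmp_path):
        trace = register.DriftTrace(
            np.array([0.0, 1.25]), np.array([0.0, -0.5]), np.array([1.0, 0.8])
        )
        path = tmp_path / "drift.csv"
        trace.to_csv(path)
        back = register.DriftTrace.from_csv(path)
        np.testing.assert_allclose(back.dx_px, trace.dx_px)
        np.testing.assert_allclose(back.dy_px, trace.dy_px)
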