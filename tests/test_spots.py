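"""Spot detection, photometry, PSF validation and quantal populations."""

import numpy as np
import pytest

from protrusion_smt import simulate
from protrusion_smt.config import SimConfig
from protrusion_smt.simulate import _gaussian_patch
from protrusion_smt.spots import (
    PSFModel,
    classify_quantal_populations,
    compare_profile_to_psf,
    detect_spots,
    line_scan_profile,
    measure_sum_intensity,
)
from tests.conftest import single_class_config

PSF = PSFModel(sigma_nm=152.0, pixel_size_nm=162.5)


def render_spot(x, y, photons, shape=(33, 33), sigma_px=PSF.sigma_px, background=0.0):
    img = np.full(shape, float(background))
    ys, xs, patch = _gaussian_patch(shape, x, y, sigma_px, photons)
    img[ys, xs] += patch
    return img


class TestPhotometry:
    def test_flat_field_sums_to_zero(self):
        img = np.full((33, 33), 7.0)
        total, background, clipped = measure_sum_intensity(
            img, (16, 16), aperture_radius=3.0, annulus_radii=(4.0, 6.0)
        )
        assert total == pytest.approx(0.0)
        assert background == pytest.approx(7.0)
        assert not clipped

    def test_encircled_energy_three_sigma(self):
        # fine pixels so the discrete aperture approximates a disk
        sigma_px = 3.0
        img = render_spot(32.2, 31.7, 10_000.0, shape=(65, 65), sigma_px=sigma_px)
        total, _, _ = measure_sum_intensity(
            img, (32.2, 31.7),
            aperture_radius=3 * sigma_px,
            annulus_radii=(5 * sigma_px, 7 * sigma_px),
        )
        expected = (1 - np.exp(-4.5)) * 10_000.0  # 0.9889 N
        assert total == pytest.approx(expected, rel=0.01)

    def test_pedestal_cancellation(self):
        sigma_px = 3.0
        img0 = render_spot(32.0, 32.0, 10_000.0, shape=(65, 65), sigma_px=sigma_px)
        imgb = img0 + 55.0
        kwargs = dict(
            aperture_radius=3 * sigma_px, annulus_radii=(5 * sigma_px, 7 * sigma_px)
        )
        t0, _, _ = measure_sum_intensity(img0, (32.0, 32.0), **kwargs)
        tb, _, _ = measure_sum_intensity(imgb, (32.0, 32.0), **kwargs)
        assert tb == pytest.approx(t0, rel=0.01)

    def test_aperture_invariance_three_vs_four_sigma(self):
        sigma_px = 3.0
        img = render_spot(32.0, 32.0, 10_000.0, shape=(65, 65), sigma_px=sigma_px)
        t3, _, _ = measure_sum_intensity(
            img, (32.0, 32.0), 3 * sigma_px, (5 * sigma_px, 7 * sigma_px)
        )
        t4, _, _ = measure_sum_intensity(
            img, (32.0, 32.0), 4 * sigma_px, (5 * sigma_px, 7 * sigma_px)
        )
        assert abs(t4 - t3) / t3 < 0.015

    def test_edge_aperture_flagged(self):
        img = np.random.default_rng(0).poisson(50, (33, 33)).astype(float)
        _, _, clipped = measure_sum_intensity(img, (1.0, 16.0), 3.0, (4.0, 6.0))
        assert clipped

    def test_bad_annulus_rejected(self):
        with pytest.raises(ValueError, match="annulus"):
            measure_sum_intensity(np.zeros((33, 33)), (16, 16), 5.0, (3.0, 6.0))


class TestDetectSpots:
    def test_single_spot_localized(self):
        rng = np.random.default_rng(2)
        img = rng.poisson(render_spot(20.3, 11.7, 1500.0, background=50.0)).astype(
            float
        )
        dets = detect_spots(img, PSF)
        assert len(dets) == 1
        d = dets[0]
        assert np.hypot(d.x_px - 20.3, d.y_px - 11.7) < 0.3

    def test_well_separated_pair(self):
        sep = 8 * PSF.sigma_px
        img = render_spot(10.0, 16.0, 1500.0, background=50.0)
        ys, xs, patch = _gaussian_patch(
            img.shape, 10.0 + sep, 16.0, PSF.sigma_px, 1500.0
        )
        img[ys, xs] += patch
        img = np.random.default_rng(3).poisson(img).astype(float)
        dets = detect_spots(img, PSF)
        assert len(dets) == 2
        xs_found = sorted(d.x_px for d in dets)
        assert xs_found[0] == pytest.approx(10.0, abs=0.3)
        assert xs_found[1] == pytest.approx(10.0 + sep, abs=0.3)

    def test_blank_frame_false_positive_rate(self):
        rng = np.random.default_rng(4)
        n_fp = 0
        for _ in range(100):
            frame = rng.poisson(50.0, (64, 64)).astype(float)
            n_fp += len(detect_spots(frame, PSF, threshold_k=5.0))
        assert n_fp / 100 < 0.1

    def test_localization_precision_at_snr10(self):
        """Mean |error| below sigma_psf / 4 for bright isolated spots."""
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(40):
            x, y = 16 + rng.uniform(-0.5, 0.5, 2)
            img = rng.poisson(render_spot(x, y, 1000.0, background=50.0)).astype(
                float
            )
            dets = detect_spots(img, PSF)
            if dets:
                d = max(dets, key=lambda d: d.amplitude)
                errs.append(np.hypot(d.x_px - x, d.y_px - y))
        assert len(errs) > 30
        assert np.mean(errs) * PSF.pixel_size_nm < PSF.sigma_nm / 4

    def test_intensity_linearity_monomer_vs_dimer(self):
        """Doubling the fluorophore count doubles the mean summed intensity."""
        means = {}
        for n_fluor in (1, 2):
            cfg = single_class_config(
                "static",
                n_molecules=1,
                n_frames=1,
                fluorophores_per_molecule=n_fluor,
                brightness_cv=0.0,
                bleach_rate=0.0,
                blink_off_rate=0.0,
                rng_seed=0,
            )
            vals = []
            for seed in range(60):
                cfg2 = SimConfig.from_dict({**cfg.to_dict(), "rng_seed": seed})
                tracks = simulate.simulate_tracks(cfg2)
                movie = simulate.render_movie(tracks, cfg2)
                dets = detect_spots(
                    movie.data[0],
                    PSFModel(cfg2.psf_sigma, cfg2.pixel_size),
                )
                dets = [d for d in dets if "clipped" not in d.flags]
                if dets:
                    vals.append(max(dets, key=lambda d: d.amplitude).sum_intensity)
            means[n_fluor] = np.mean(vals)
        assert means[2] / means[1] == pytest.approx(2.0, abs=0.1)


class TestLineScanPSF:
    def test_exact_model_curve_self_consistency(self):
        grid = np.linspace(-600, 600, 241)
        curve = np.exp(-(grid**2) / (2 * PSF.sigma_nm**2))
        comp = compare_profile_to_psf([(grid, curve)] * 3, PSF)
        assert comp.fitted_sigma_nm == pytest.approx(PSF.sigma_nm, rel=1e-3)
        assert comp.rms_discrepancy < 1e-3  # grid interpolation only
        assert not comp.flagged

    def test_rendered_point_emitters_match_psf(self):
        rng = np.random.default_rng(6)
        profiles = []
        for _ in range(10):
            x, y = 16 + rng.uniform(-0.5, 0.5, 2)
            img = rng.poisson(render_spot(x, y, 2000.0, background=30.0)).astype(
                float
            )
            profiles.append(
                line_scan_profile(
                    img, (x, y), half_length_px=5, pixel_size_nm=PSF.pixel_size_nm
                )
            )
        comp = compare_profile_to_psf(profiles, PSF, correct_pixelation=True)
        assert abs(comp.fitted_sigma_nm - PSF.sigma_nm) / PSF.sigma_nm < 0.05
        assert not comp.flagged

    def test_doublet_flagged(self):
        sep = PSF.sigma_px  # emitters at +/- sigma: 2-sigma separation
        img = render_spot(16 - sep, 16.0, 5000.0)
        ys, xs, patch = _gaussian_patch(
            img.shape, 16 + sep, 16.0, PSF.sigma_px, 5000.0
        )
        img[ys, xs] += patch
        prof = line_scan_profile(
            img, (16.0, 16.0), half_length_px=6, pixel_size_nm=PSF.pixel_size_nm
        )
        comp = compare_profile_to_psf([prof] * 3, PSF, correct_pixelation=True)
        assert comp.width_excess > 0.2
        assert comp.flagged


class TestQuantalPopulations:
    def test_two_populations_at_printed_intensities(self):
        """Clusters at the measured one- and two-fluorophore intensities."""
        rng = np.random.default_rng(7)
        x = np.concatenate(
            [rng.normal(34.0, 10.0, 100), rng.normal(76.0, 10.0, 100)]
        )
        fit = classify_quantal_populations(x, k_max=3)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(34.0, rel=0.10)
        assert fit.means[1] == pytest.approx(76.0, rel=0.10)
        assert 1.9 <= fit.mean_ratio <= 2.5

    def test_identical_intensities_single_population(self):
        fit = classify_quantal_populations(np.full(20, 42.0))
        assert fit.k == 1
        assert fit.quantal_intensity == 42.0
        assert fit.sds[0] == 0.0
        assert fit.mean_ratio is None

    def test_three_quantal_levels(self):
        rng = np.random.default_rng(8)
        q = 100.0
        x = np.concatenate(
            [rng.normal(m * q, 0.1 * m * q, 150) for m in (1, 2, 3)]
        )
        fit = classify_quantal_populations(x, k_max=4)
        assert fit.k == 3
        ratios = fit.means / fit.means[0]
        np.testing.assert_allclose(ratios, [1, 2, 3], rtol=0.05)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(30, 5, 40), rng.normal(60, 5, 40)])
        fit = classify_quantal_populations(x)
        assert fit.counts.sum() == 80
        assert np.all(np.diff(fit.means) > 0)

    def test_too_few_intensities_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            classify_quantal_populations(np.arange(5.0))

    def test_quantal_constrained_mode(self):
        rng = np.random.default_rng(10)
        q = 50.0
        x = np.concatenate([rng.normal(q, 5, 80), rng.normal(2 * q, 5, 80)])
        fit = classify_quantal_populations(x, k_max=3, mode="quantal")
        assert fit.k == 2
        assert fit.quantal_intensity == pytest.approx(q, rel=0.08)
        assert fit.mean_ratio == pytest.approx(2.0)
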