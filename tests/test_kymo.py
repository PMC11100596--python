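"""Kymograph construction, linking, axis projection and classification."""

import numpy as np
import pytest

from protrusion_smt import simulate
from protrusion_smt.config import SimConfig
from protrusion_smt.io import Movie
from protrusion_smt.kymo import (
    AxisPolyline,
    ClassifierConfig,
    Trajectory,
    build_kymograph,
    classify_trajectory,
    link_trajectories,
    project_onto_axis,
    ridge_velocity,
)
from protrusion_smt.spots import Detection
from tests.conftest import single_class_config

PX = 162.5


def det(frame, x, y, index, s=np.nan, width=150.0):
    return Detection(
        frame=frame, x_px=x, y_px=y, sum_intensity=100.0, local_background=0.0,
        fit_sigma_nm=width, snr=10.0, s_nm=s, index=index,
    )


def series_trajectory(s_values, dt=1.0, width=150.0):
    dets = [
        det(i, 0.0, 0.0, i, s=si, width=width) for i, si in enumerate(s_values)
    ]
    tr = Trajectory(track_id=0, detections=dets)
    tr.set_times(dt)
    return tr


class TestAxisPolyline:
    def test_straight_axis_fractions(self):
        axis = AxisPolyline.from_endpoints((0, 0), (40, 0), PX)
        L = axis.arc_length_nm
        for frac in (0.0, 0.5, 1.0):
            s, d = axis.project(40 * frac, 0.0)
            assert s == pytest.approx(frac * L)
            assert d == pytest.approx(0.0)

    def test_perpendicular_bisector_projects_to_midpoint(self):
        axis = AxisPolyline.from_endpoints((0, 0), (10, 0), PX)
        s, d = axis.project(5.0, 3.0)
        assert s == pytest.approx(0.5 * axis.arc_length_nm)
        assert d == pytest.approx(3.0)

    def test_polyline_arc_length(self):
        axis = AxisPolyline(np.array([[0, 0], [3, 4], [3, 10]]), PX)
        assert axis.arc_length_nm == pytest.approx((5 + 6) * PX)

    def test_csv_roundtrip(self, tmp_path):
        axis = AxisPolyline(np.array([[1.5, 2.5], [10.0, 4.0]]), PX)
        path = tmp_path / "axis.csv"
        axis.to_csv(path)
        back = AxisPolyline.from_csv(path, PX)
        np.testing.assert_allclose(back.vertices_px, axis.vertices_px)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            AxisPolyline(np.array([[1.0, 1.0]]), PX)


class TestBuildKymograph:
    def test_uniform_movie_constant(self):
        movie = Movie(np.full((5, 32, 48), 3.0), PX, 1.0)
        axis = AxisPolyline.from_endpoints((5, 16), (40, 16), PX)
        for reducer in ("max", "mean"):
            k = build_kymograph(movie, axis, reducer=reducer)
            np.testing.assert_allclose(k.data, 3.0)

    def test_static_spot_is_time_parallel_ridge(self):
        cfg = single_class_config(
            "static", n_molecules=1, n_frames=10, brightness_cv=0.0,
            bleach_rate=0.0, blink_off_rate=0.0, rng_seed=1,
        )
        tracks = simulate.simulate_tracks(cfg)
        movie = simulate.render_movie(tracks, cfg, deterministic=True)
        p0, p1 = cfg.axis_endpoints_px
        axis = AxisPolyline.from_endpoints(tuple(p0), tuple(p1), cfg.pixel_size)
        k = build_kymograph(movie, axis)
        ridge_bins = np.nanargmax(k.data, axis=0)
        assert np.all(ridge_bins == ridge_bins[0])
        expected_bin = round(tracks[0].s_nm[0] / k.bin_size_nm)
        assert abs(int(ridge_bins[0]) - expected_bin) <= 1

    def test_processive_ridge_slope_matches_velocity(self):
        cfg = single_class_config(
            "processive", n_molecules=1, n_frames=25, velocity_mean=200.0,
            velocity_sd=0.0, bleach_rate=0.0, blink_off_rate=0.0, rng_seed=2,
        )
        tracks = simulate.simulate_tracks(cfg)
        movie = simulate.render_movie(tracks, cfg)
        p0, p1 = cfg.axis_endpoints_px
        axis = AxisPolyline.from_endpoints(tuple(p0), tuple(p1), cfg.pixel_size)
        k = build_kymograph(movie, axis)
        v, _, _ = ridge_velocity(k)
        assert v == pytest.approx(200.0, rel=0.05)

    def test_mean_reduced_below_max_reduced(self):
        cfg = SimConfig(n_molecules=4, n_frames=5, rng_seed=3)
        movie = simulate.render_movie(simulate.simulate_tracks(cfg), cfg)
        p0, p1 = cfg.axis_endpoints_px
        axis = AxisPolyline.from_endpoints(tuple(p0), tuple(p1), cfg.pixel_size)
        kmax = build_kymograph(movie, axis, reducer="max")
        kmean = build_kymograph(movie, axis, reducer="mean")
        valid = np.isfinite(kmax.data) & np.isfinite(kmean.data)
        assert np.all(kmean.data[valid] <= kmax.data[valid] + 1e-9)


class TestLinking:
    def test_single_molecule_single_track(self):
        dets = [det(f, 10.0 + 0.1 * f, 8.0, f) for f in range(10)]
        tracks = link_trajectories(dets, pixel_size_nm=PX)
        assert len(tracks) == 1
        assert tracks[0].n_detections == 10

    def test_distant_molecules_not_cross_linked(self):
        dets = []
        for f in range(5):
            dets.append(det(f, 5.0, 8.0, 2 * f))
            dets.append(det(f, 55.0, 8.0, 2 * f + 1))
        tracks = link_trajectories(dets, max_disp_nm=650.0, pixel_size_nm=PX)
        assert len(tracks) == 2
        assert all(t.n_detections == 5 for t in tracks)

    @pytest.mark.parametrize("gap,expected_tracks", [(2, 1), (3, 2)])
    def test_gap_bridging_boundary(self, gap, expected_tracks):
        """Blinking gap == max_gap bridges; max_gap + 1 splits."""
        frames = [0, 1, 2] + [3 + gap, 4 + gap, 5 + gap]
        dets = [det(f, 10.0, 8.0, i) for i, f in enumerate(frames)]
        tracks = link_trajectories(dets, max_gap=2, pixel_size_nm=PX)
        assert len(tracks) == expected_tracks

    def test_linking_conserves_detections(self):
        rng = np.random.default_rng(4)
        dets = [
            det(int(f), float(x), float(y), i)
            for i, (f, x, y) in enumerate(
                zip(rng.integers(0, 20, 120), rng.uniform(0, 60, 120),
                    rng.uniform(0, 30, 120))
            )
        ]
        tracks = link_trajectories(dets, pixel_size_nm=PX)
        seen = [d.index for t in tracks for d in t.detections]
        assert sorted(seen) == sorted(d.index for d in dets)
        assert len(seen) == len(set(seen))

    def test_deterministic_given_input_order(self):
        rng = np.random.default_rng(5)
        dets = [
            det(int(f), float(x), 5.0, i)
            for i, (f, x) in enumerate(
                zip(rng.integers(0, 10, 40), rng.uniform(0, 40, 40))
            )
        ]
        a = link_trajectories(dets, pixel_size_nm=PX)
        b = link_trajectories(dets, pixel_size_nm=PX)
        assert [
            [d.index for d in t.detections] for t in a
        ] == [[d.index for d in t.detections] for t in b]


class TestProjection:
    def test_projection_assigns_s(self):
        axis = AxisPolyline.from_endpoints((0, 0), (40, 0), PX)
        tr = Trajectory(
            track_id=0, detections=[det(0, 10.0, 0.5, 0), det(1, 20.0, -0.5, 1)]
        )
        project_onto_axis(tr, axis)
        assert tr.s_nm[0] == pytest.approx(10 * PX)
        assert tr.s_nm[1] == pytest.approx(20 * PX)

    def test_off_axis_points_flagged(self):
        axis = AxisPolyline.from_endpoints((0, 0), (40, 0), PX, line_width_px=3)
        tr = Trajectory(track_id=0, detections=[det(0, 10.0, 30.0, 0)])
        project_onto_axis(tr, axis)
        assert "off_axis" in tr.detections[0].flags
        assert np.isnan(tr.s_nm[0])


class TestClassifyTrajectory:
    def test_constant_series_is_static(self):
        rng = np.random.default_rng(6)
        tr = series_trajectory(1000 + rng.normal(0, 20, 30))
        assert classify_trajectory(tr, 20.0) == "static"

    def test_linear_series_is_processive(self):
        rng = np.random.default_rng(7)
        tr = series_trajectory(100.0 * np.arange(20) + rng.normal(0, 20, 20))
        assert classify_trajectory(tr, 20.0) == "processive"

    def test_single_frame_is_transient(self):
        tr = series_trajectory([500.0])
        assert classify_trajectory(tr, 20.0) == "transient"

    def test_staircase_is_stepwise(self):
        rng = np.random.default_rng(8)
        s = np.concatenate([np.zeros(8), np.full(8, 150.0), np.full(8, 300.0)])
        tr = series_trajectory(s + rng.normal(0, 20, s.size))
        assert classify_trajectory(tr, 20.0) == "stepwise"

    def test_noiseless_ramp_is_processive_not_stepwise(self):
        tr = series_trajectory(50.0 * np.arange(30))
        assert classify_trajectory(tr, 20.0) == "processive"

    def test_blurred_wide_track_is_transient(self):
        rng = np.random.default_rng(9)
        tr = series_trajectory(rng.uniform(0, 500, 6), width=260.0)
        cfg = ClassifierConfig(psf_sigma_nm=152.0)
        assert classify_trajectory(tr, 20.0, config=cfg) == "transient"

    def test_retrograde_ramp_is_unclassified(self):
        rng = np.random.default_rng(10)
        tr = series_trajectory(3000 - 100.0 * np.arange(20) + rng.normal(0, 20, 20))
        assert classify_trajectory(tr, 20.0) == "unclassified"
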