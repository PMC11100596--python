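"""End-to-end orchestration: simulate/load -> register -> detect -> track.

``run_pipeline`` executes the full chain from one :class:`RunConfig`,
writes every intermediate artifact into a run directory (corrected
movie, drift trace, detections, trajectories, kymograph, motion
summary), and — when the movie was simulated and ground truth is
available — matches estimated trajectories to true molecules and
produces a :class:`RecoveryReport` with per-class confusion counts and
accuracy metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from protrusion_smt import register, simulate
from protrusion_smt.config import RunConfig, SimConfig, _jsonify
from protrusion_smt.io import Movie, read_movie, write_movie
from protrusion_smt.kymo import (
    AxisPolyline,
    ClassifierConfig,
    Trajectory,
    build_kymograph,
    classify_trajectory,
    link_trajectories,
    project_onto_axis,
    trajectories_to_frame,
)
from protrusion_smt.motility import (
    detect_steps,
    step_statistics,
    steps_to_frame,
    summarize_velocities,
)
from protrusion_smt.spots import PSFModel, detect_spots, detections_to_frame

logger = logging.getLogger(__name__)

# simulator motion class -> expected trajectory class
TRUTH_TO_ESTIMATE_CLASS = {
    "static": "static",
    "diffusive": "transient",
    "processive": "processive",
    "stepper": "stepwise",
}


@dataclass
class TrackMatch:
    truth_id: int
    track_id: int
    mean_dist_nm: float
    overlap_frames: int


@dataclass
class RecoveryReport:
    """Ground-truth comparison of one pipeline run."""

    confusion: dict[str, dict[str, int]]  # truth class -> predicted class -> n
    recall: dict[str, float]
    matches: list[TrackMatch]
    n_truth: int
    n_tracks: int
    n_matched: int
    detection_recall: float
    detection_precision: float
    drift_rmse_px: float | None = None
    velocity_bias_nm_s: float | None = None
    velocity_sd_error_nm_s: float | None = None
    step_size_bias_nm: float | None = None
    quantal_ratio: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matches"] = [dataclasses.asdict(m) for m in self.matches]
        return _jsonify(d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def match_tracks_to_truth(
    trajectories: list[Trajectory],
    truth_tracks: list[simulate.GroundTruthTrack],
    config: SimConfig,
    max_match_dist_nm: float = 500.0,
) -> list[TrackMatch]:
    """One-to-one greedy matching of estimated tracks to true molecules.

    Candidate pairs are scored by mean distance over their temporal
    overlap divided by the overlap length, so long faithful tracks win
    over short coincidental ones; pairs whose 75th-percentile per-frame
    distance exceeds ``max_match_dist_nm`` are ineligible (a quantile,
    not the maximum, so isolated contaminated links do not disqualify an
    otherwise faithful track).
    Unmatched truths are misses, unmatched estimates are false tracks.
    """
    candidates = []
    for truth in truth_tracks:
        xy_true = truth.xy_px(config)
        xy_sub = truth.xy_sub_px(config)  # exposure path of diffusive molecules
        visible = truth.n_active > 0
        for tr in trajectories:
            frames = tr.frames
            in_range = (frames >= 0) & (frames < config.n_frames)
            overlap_mask = in_range & visible[np.clip(frames, 0, config.n_frames - 1)]
            if not overlap_mask.any():
                continue
            fr = frames[overlap_mask]
            if xy_sub is not None:
                # a blurred detection may localize any part of the
                # exposure path: take the closest sub-frame position
                dx = tr.x_px[overlap_mask][:, None] - xy_sub[fr, :, 0]
                dy = tr.y_px[overlap_mask][:, None] - xy_sub[fr, :, 1]
                dists = np.hypot(dx, dy).min(axis=1) * config.pixel_size
            else:
                dx = tr.x_px[overlap_mask] - xy_true[fr, 0]
                dy = tr.y_px[overlap_mask] - xy_true[fr, 1]
                dists = np.hypot(dx, dy) * config.pixel_size
            mean_dist = float(dists.mean())
            overlap = int(overlap_mask.sum())
            if float(np.percentile(dists, 75)) <= max_match_dist_nm:
                candidates.append(
                    TrackMatch(
                        truth_id=truth.molecule_id,
                        track_id=tr.track_id,
                        mean_dist_nm=mean_dist,
                        overlap_frames=overlap,
                    )
                )
    candidates.sort(
        key=lambda m: (m.mean_dist_nm / m.overlap_frames, m.truth_id, m.track_id)
    )
    used_truth: set[int] = set()
    used_track: set[int] = set()
    matches = []
    for cand in candidates:
        if cand.truth_id in used_truth or cand.track_id in used_track:
            continue
        matches.append(cand)
        used_truth.add(cand.truth_id)
        used_track.add(cand.track_id)
    return matches


def build_recovery_report(
    trajectories: list[Trajectory],
    truth_tracks: list[simulate.GroundTruthTrack],
    config: SimConfig,
    max_match_dist_nm: float = 500.0,
    drift_trace: register.DriftTrace | None = None,
    warnings_list: list[str] | None = None,
) -> RecoveryReport:
    matches = match_tracks_to_truth(
        trajectories, truth_tracks, config, max_match_dist_nm
    )
    by_track = {tr.track_id: tr for tr in trajectories}
    by_truth = {tr.molecule_id: tr for tr in truth_tracks}
    classes_t = sorted({t.motion_class for t in truth_tracks})
    confusion: dict[str, dict[str, int]] = {
        c: {"missed": 0} for c in classes_t
    }
    for truth in truth_tracks:
        confusion[truth.motion_class].setdefault("missed", 0)
    matched_truths = {m.truth_id for m in matches}
    for m in matches:
        pred = by_track[m.track_id].motion_class
        row = confusion[by_truth[m.truth_id].motion_class]
        row[pred] = row.get(pred, 0) + 1
    for truth in truth_tracks:
        if truth.molecule_id not in matched_truths:
            confusion[truth.motion_class]["missed"] += 1
    recall = {}
    for cls in classes_t:
        expected = TRUTH_TO_ESTIMATE_CLASS.get(cls, cls)
        total = sum(confusion[cls].values())
        recall[cls] = confusion[cls].get(expected, 0) / total if total else np.nan

    # per-frame detection recall/precision against visible truth positions
    n_true_pos = 0
    n_det = sum(tr.n_detections for tr in trajectories)
    n_hit = 0
    match_px = max_match_dist_nm / config.pixel_size
    det_xy: dict[int, list[tuple[float, float]]] = {}
    for tr in trajectories:
        for det in tr.detections:
            det_xy.setdefault(det.frame, []).append((det.x_px, det.y_px))
    for truth in truth_tracks:
        xy = truth.xy_px(config)
        for t in np.nonzero(truth.n_active > 0)[0]:
            n_true_pos += 1
            for x, y in det_xy.get(int(t), []):
                if np.hypot(x - xy[t, 0], y - xy[t, 1]) <= match_px:
                    n_hit += 1
                    break
    det_recall = n_hit / n_true_pos if n_true_pos else np.nan

    # precision: fraction of detections near any visible truth
    n_det_hit = 0
    truth_xy_by_frame: dict[int, np.ndarray] = {}
    for t in range(config.n_frames):
        pts = [
            truth.xy_px(config)[t]
            for truth in truth_tracks
            if truth.n_active[t] > 0
        ]
        truth_xy_by_frame[t] = np.asarray(pts) if pts else np.empty((0, 2))
    for tr in trajectories:
        for det in tr.detections:
            pts = truth_xy_by_frame.get(det.frame, np.empty((0, 2)))
            if pts.size and np.min(
                np.hypot(pts[:, 0] - det.x_px, pts[:, 1] - det.y_px)
            ) <= match_px:
                n_det_hit += 1
    det_precision = n_det_hit / n_det if n_det else np.nan

    # velocity recovery over matched processive molecules
    vel_bias = None
    vel_sd_err = None
    true_v, est_v = [], []
    for m in matches:
        truth = by_truth[m.truth_id]
        tr = by_track[m.track_id]
        if truth.motion_class == "processive" and tr.n_detections >= 3:
            s = tr.s_nm
            keep = np.isfinite(s)
            if keep.sum() >= 3:
                from protrusion_smt.motility import estimate_velocity

                est = estimate_velocity(
                    s[keep], tr.frames[keep] * config.frame_interval
                )
                true_v.append(truth.velocity_nm_s)
                est_v.append(est.velocity_nm_s)
    if true_v:
        true_v = np.asarray(true_v)
        est_v = np.asarray(est_v)
        vel_bias = float(np.mean(est_v - true_v))
        if true_v.size >= 2:
            vel_sd_err = float(est_v.std(ddof=1) - true_v.std(ddof=1))

    drift_rmse = None
    if drift_trace is not None and not trace_is_trivial(drift_trace):
        drift_rmse = float(
            np.sqrt(np.mean(drift_trace.dx_px**2 + drift_trace.dy_px**2))
        )

    report = RecoveryReport(
        confusion=confusion,
        recall=recall,
        matches=matches,
        n_truth=len(truth_tracks),
        n_tracks=len(trajectories),
        n_matched=len(matches),
        detection_recall=float(det_recall),
        detection_precision=float(det_precision),
        drift_rmse_px=drift_rmse,
        velocity_bias_nm_s=vel_bias,
        velocity_sd_error_nm_s=vel_sd_err,
        warnings=warnings_list or [],
    )
    return report


def trace_is_trivial(trace: register.DriftTrace) -> bool:
    return bool(np.all(trace.dx_px == 0) and np.all(trace.dy_px == 0))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain; returns a dict of artifacts.

    Keys: ``movie``, ``corrected``, ``trace``, ``detections``,
    ``trajectories``, ``kymograph``, ``velocity_summary``, ``steps``,
    ``report`` (None without ground truth), ``out_dir``.  Every stage is
    deterministic given the config seed; outputs are stamped with the
    config hash.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    warnings_list: list[str] = []
    try:
        if config.sim is not None:
            stage = "simulate"
            sim = dataclasses.replace(config.sim, rng_seed=config.seed)
            truth_tracks = simulate.simulate_tracks(sim)
            movie = simulate.render_movie(
                truth_tracks, sim, deterministic=config.deterministic_render
            )
            simulate.write_ground_truth(truth_tracks, sim, out_dir / "truth.csv")
            write_movie(movie, out_dir / "movie.tif")
            p0, p1 = sim.axis_endpoints_px
            axis = AxisPolyline.from_endpoints(
                tuple(p0), tuple(p1), sim.pixel_size, config.line_width_px
            )
            pixel_size = sim.pixel_size
            frame_interval = sim.frame_interval
            psf = PSFModel(sigma_nm=sim.psf_sigma, pixel_size_nm=pixel_size)
        else:
            stage = "load"
            movie = read_movie(config.movie_path)
            truth_tracks = None
            sim = None
            pixel_size = movie.pixel_size_nm
            frame_interval = movie.frame_interval_s
            axis = AxisPolyline.from_csv(
                config.axis_csv, pixel_size, config.line_width_px
            )
            psf = PSFModel.from_optics(pixel_size_nm=pixel_size)

        stage = "register"
        if config.correct_drift and movie.n_frames >= 2:
            trace = register.estimate_drift(
                movie, reference_mode=config.reference_mode
            )
            corrected = register.apply_drift_correction(movie, trace)
            if trace.low_confidence.any():
                warnings_list.append(
                    f"{int(trace.low_confidence.sum())} low-confidence drift frames"
                )
        else:
            trace = register.DriftTrace(
                dx_px=np.zeros(movie.n_frames),
                dy_px=np.zeros(movie.n_frames),
                peak=np.ones(movie.n_frames),
            )
            corrected = movie
        trace.to_csv(out_dir / "drift.csv")
        write_movie_safe(corrected, out_dir / "corrected.tif", warnings_list)

        stage = "spots"
        detections = []
        for t in range(corrected.n_frames):
            dets = detect_spots(
                corrected.data[t], psf, threshold_k=config.threshold_k,
                frame_index=t,
            )
            detections.extend(dets)
        for i, det in enumerate(detections):
            det.index = i
        n_clipped = sum("clipped" in d.flags for d in detections)
        if n_clipped:
            warnings_list.append(f"{n_clipped} clipped photometry apertures")

        stage = "track"
        trajectories = link_trajectories(
            detections,
            max_disp_nm=config.max_disp_nm,
            max_gap=config.max_gap,
            pixel_size_nm=pixel_size,
        )
        cls_cfg = ClassifierConfig(
            bic_penalty=config.bic_penalty, psf_sigma_nm=psf.sigma_nm
        )
        for tr in trajectories:
            project_onto_axis(tr, axis)
            tr.set_times(frame_interval)
            classify_trajectory(
                tr, config.localization_sd_nm, frame_interval, cls_cfg
            )
        detections_to_frame(detections).to_csv(out_dir / "detections.csv", index=False)
        trajectories_to_frame(trajectories).to_csv(out_dir / "tracks.csv", index=False)

        stage = "kymo"
        kymograph = build_kymograph(
            corrected, axis, reducer=config.reducer, bin_size_nm=config.kymo_bin_nm
        )
        kymo_dir = out_dir / "kymo"
        kymo_dir.mkdir(exist_ok=True)
        kymograph.to_tiff(kymo_dir / "kymograph.tif")

        stage = "motility"
        vel_summary = summarize_velocities(trajectories)
        from protrusion_smt.motility import is_undersampled

        n_under = sum(
            is_undersampled(v, frame_interval, config.max_disp_nm)
            for v in vel_summary.velocities_nm_s
        )
        if n_under:
            warnings_list.append(
                f"{n_under} track(s) faster than the linking radius allows: "
                "under-sampled, shorten the frame interval"
            )
        all_steps = []
        for tr in trajectories:
            if tr.motion_class == "stepwise" and tr.n_detections >= 5:
                s = tr.s_nm
                keep = np.isfinite(s)
                if keep.sum() >= 5:
                    all_steps.extend(
                        detect_steps(
                            s[keep],
                            tr.frames[keep] * frame_interval,
                            penalty=config.bic_penalty,
                            min_step_nm=2 * config.localization_sd_nm,
                            track_id=tr.track_id,
                        )
                    )
        steps_to_frame(all_steps).to_csv(out_dir / "steps.csv", index=False)
        step_stats = step_statistics(all_steps)
        summary = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_detections": len(detections),
            "n_trajectories": len(trajectories),
            "class_counts": {
                cls: sum(tr.motion_class == cls for tr in trajectories)
                for cls in sorted({tr.motion_class for tr in trajectories})
            },
            "velocity": vel_summary.to_dict(),
            "steps": {
                "mean_size_nm": step_stats.mean_size_nm,
                "sd_size_nm": step_stats.sd_size_nm,
                "mean_dwell_s": step_stats.mean_dwell_s,
                "n": step_stats.n,
            },
            "warnings": warnings_list,
        }
        (out_dir / "summary.json").write_text(
            json.dumps(_jsonify(summary), indent=2, allow_nan=True)
        )

        stage = "report"
        report = None
        if truth_tracks is not None:
            report = build_recovery_report(
                trajectories,
                truth_tracks,
                sim,
                max_match_dist_nm=config.max_match_dist_nm,
                drift_trace=trace,
                warnings_list=warnings_list,
            )
            report.to_json(out_dir / "report.json")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    logger.info("pipeline finished: %d trajectories", len(trajectories))
    return {
        "movie": movie,
        "corrected": corrected,
        "trace": trace,
        "detections": detections,
        "trajectories": trajectories,
        "kymograph": kymograph,
        "velocity_summary": vel_summary,
        "steps": all_steps,
        "report": report,
        "truth_tracks": truth_tracks,
        "out_dir": out_dir,
    }


def write_movie_safe(movie: Movie, path: Path, warnings_list: list[str]) -> None:
    try:
        write_movie(movie, path)
    except ValueError as exc:
        warnings_list.append(f"could not write {path.name}: {exc}")
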