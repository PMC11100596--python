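"""Kymographs, trajectory linking and motion classification.

A kymograph resamples each movie frame along the protrusion axis
(a polyline from base to tip) into a (distance, time) map: a static
molecule draws a line parallel to the time axis, a processive motor a
sloped ridge, a stepper a staircase.  Detections are linked into
trajectories by deterministic greedy nearest-neighbor assignment with
gap bridging (fluorophore blinking), projected onto the axis to get
s(t), and classified into the phenotypes seen in kymographs of motor
constructs: static, transient (gone after ~1 frame, as freely diffusing
molecules are), processive (continuous tip-ward ramp) or stepwise
(staircase), by nested-model comparison under the Bayesian information
criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from protrusion_smt.io import Movie
from protrusion_smt.motility import (
    estimate_velocity,
    fit_piecewise_constant,
    fit_steps,
)
from protrusion_smt.spots import Detection

TRAJECTORY_CLASSES = (
    "static",
    "transient",
    "processive",
    "stepwise",
    "unclassified",
)


@dataclass
class AxisPolyline:
    """Protrusion axis: ordered vertices in px, base first, tip last."""

    vertices_px: np.ndarray  # (n, 2) rows of (x, y)
    pixel_size_nm: float
    line_width_px: int = 3

    def __post_init__(self) -> None:
        self.vertices_px = np.asarray(self.vertices_px, dtype=float)
        if self.vertices_px.ndim != 2 or self.vertices_px.shape[0] < 2:
            raise ValueError("axis needs at least 2 vertices")
        if self.arc_length_nm <= 0:
            raise ValueError("axis arc length must be positive")

    @property
    def segment_lengths_px(self) -> np.ndarray:
        d = np.diff(self.vertices_px, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def arc_length_nm(self) -> float:
        return float(self.segment_lengths_px.sum() * self.pixel_size_nm)

    def sample(self, spacing_px: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Points every ``spacing_px`` along the polyline.

        Returns (s_nm, points_px (n,2), unit tangents (n,2)).
        """
        seg = self.segment_lengths_px
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        s_px = np.arange(0.0, total + spacing_px / 2, spacing_px)
        s_px = s_px[s_px <= total + 1e-9]
        idx = np.clip(np.searchsorted(cum, s_px, side="right") - 1, 0, len(seg) - 1)
        t = (s_px - cum[idx]) / seg[idx]
        p0 = self.vertices_px[idx]
        p1 = self.vertices_px[idx + 1]
        pts = p0 + t[:, None] * (p1 - p0)
        tangents = (p1 - p0) / seg[idx][:, None]
        return s_px * self.pixel_size_nm, pts, tangents

    def project(self, x_px: float, y_px: float) -> tuple[float, float]:
        """Arc-length coordinate (nm) and distance (px) of nearest axis point."""
        p = np.array([x_px, y_px])
        seg = self.segment_lengths_px
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        best_d, best_s = np.inf, 0.0
        for i in range(len(seg)):
            a = self.vertices_px[i]
            b = self.vertices_px[i + 1]
            ab = b - a
            t = float(np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0))
            q = a + t * ab
            d = float(np.hypot(*(p - q)))
            if d < best_d:
                best_d = d
                best_s = cum[i] + t * seg[i]
        return best_s * self.pixel_size_nm, best_d

    @classmethod
    def from_endpoints(
        cls,
        p0: tuple[float, float],
        p1: tuple[float, float],
        pixel_size_nm: float,
        line_width_px: int = 3,
    ) -> "AxisPolyline":
        return cls(
            vertices_px=np.array([p0, p1], dtype=float),
            pixel_size_nm=pixel_size_nm,
            line_width_px=line_width_px,
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, pixel_size_nm: float, line_width_px: int = 3
    ) -> "AxisPolyline":
        """Two-column CSV of vertices (x_px, y_px), base first."""
        df = pd.read_csv(path)
        cols = df.columns[:2]
        return cls(
            vertices_px=df[cols].to_numpy(dtype=float),
            pixel_size_nm=pixel_size_nm,
            line_width_px=line_width_px,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.vertices_px, columns=["x_px", "y_px"]).to_csv(
            path, index=False
        )


@dataclass
class Kymograph:
    """(distance-bin, frame) intensity map for one protrusion axis."""

    data: np.ndarray
    bin_size_nm: float
    frame_interval_s: float
    axis: AxisPolyline | None = None
    reducer: str = "max"

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.data.astype(np.float32), imagej=True)

    def to_png(self, path: str | Path, cmap: str = "magma") -> None:
        """Display render: time on the horizontal axis, base at bottom."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        extent = (
            0.0,
            self.n_frames * self.frame_interval_s,
            0.0,
            self.n_bins * self.bin_size_nm / 1000.0,
        )
        shown = np.ma.masked_invalid(self.data)
        ax.imshow(
            shown, origin="lower", aspect="auto", extent=extent, cmap=cmap
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("distance from base (um)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_kymograph(
    movie: Movie,
    axis: AxisPolyline,
    reducer: str = "max",
    bin_size_nm: float | None = None,
    line_width_px: int | None = None,
) -> Kymograph:
    """Sample the movie along the axis into a kymograph.

    At each distance bin the intensity is interpolated bilinearly at
    ``line_width_px`` positions across the perpendicular and combined
    with ``reducer`` ('max' default, 'mean' optional).  Samples outside
    the field become NaN sentinels.
    """
    from scipy import ndimage

    if reducer not in ("max", "mean"):
        raise ValueError("reducer must be 'max' or 'mean'")
    if bin_size_nm is None:
        bin_size_nm = movie.pixel_size_nm
    width = line_width_px if line_width_px is not None else axis.line_width_px
    spacing_px = bin_size_nm / movie.pixel_size_nm
    _, pts, tangents = axis.sample(spacing_px)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(width) - (width - 1) / 2.0
    # coords shape: (2, n_offsets, n_bins) as (row=y, col=x)
    xs = pts[None, :, 0] + offsets[:, None] * normals[None, :, 0]
    ys = pts[None, :, 1] + offsets[:, None] * normals[None, :, 1]
    h, w = movie.shape
    outside = (xs < -0.5) | (xs > w - 0.5) | (ys < -0.5) | (ys > h - 0.5)
    if outside.all():
        raise ValueError("axis lies fully outside the field")
    n_bins = pts.shape[0]
    out = np.empty((n_bins, movie.n_frames), dtype=np.float64)
    warned = False
    for t in range(movie.n_frames):
        frame = movie.data[t]
        nan_mask = ~np.isfinite(frame)
        filled = np.where(nan_mask, 0.0, frame)
        vals = ndimage.map_coordinates(
            filled, [ys.ravel(), xs.ravel()], order=1, mode="nearest"
        ).reshape(ys.shape)
        if nan_mask.any():
            bad = ndimage.map_coordinates(
                nan_mask.astype(float), [ys.ravel(), xs.ravel()], order=1,
                mode="constant", cval=1.0,
            ).reshape(ys.shape) > 0
        else:
            bad = np.zeros_like(vals, dtype=bool)
        bad |= outside
        vals[bad] = np.nan
        if bad.any() and not warned:
            if outside.any() or nan_mask.any():
                warnings.warn(
                    "axis samples fall outside the (corrected) field; "
                    "affected bins are NaN",
                    stacklevel=2,
                )
                warned = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[:, t] = (
                np.nanmax(vals, axis=0) if reducer == "max"
                else np.nanmean(vals, axis=0)
            )
    return Kymograph(
        data=out,
        bin_size_nm=bin_size_nm,
        frame_interval_s=movie.frame_interval_s,
        axis=axis,
        reducer=reducer,
    )


def ridge_velocity(
    kymograph: Kymograph, min_peak_snr: float = 3.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Velocity (nm/s) of the dominant sloped ridge in a kymograph.

    Per frame, the ridge position is the intensity-weighted centroid in
    a +/-2-bin window around the maximum; frames without a significant
    peak (below median + ``min_peak_snr`` robust SDs) are skipped.  The
    velocity is the OLS slope of ridge position against time.
    """
    data = kymograph.data
    med = np.nanmedian(data)
    mad = np.nanmedian(np.abs(data - med)) * 1.4826
    thr = med + min_peak_snr * (mad if mad > 0 else np.nanstd(data))
    s_list, t_list = [], []
    for t in range(kymograph.n_frames):
        col = data[:, t]
        if not np.any(np.isfinite(col)):
            continue
        i = int(np.nanargmax(col))
        if not col[i] > thr:
            continue
        lo, hi = max(0, i - 2), min(len(col), i + 3)
        win = col[lo:hi] - med
        win = np.where(np.isfinite(win) & (win > 0), win, 0.0)
        if win.sum() == 0:
            centroid = float(i)
        else:
            centroid = float((np.arange(lo, hi) * win).sum() / win.sum())
        s_list.append(centroid * kymograph.bin_size_nm)
        t_list.append(t * kymograph.frame_interval_s)
    if len(s_list) < 3:
        raise ValueError("fewer than 3 ridge points above threshold")
    est = estimate_velocity(np.asarray(s_list), np.asarray(t_list))
    return est.velocity_nm_s, np.asarray(t_list), np.asarray(s_list)


@dataclass
class Trajectory:
    """Time-ordered detections of one putative molecule."""

    track_id: int
    detections: list[Detection]
    motion_class: str = "unclassified"

    def __post_init__(self) -> None:
        frames = self.frames
        if np.any(np.diff(frames) <= 0):
            raise ValueError("detection frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def x_px(self) -> np.ndarray:
        return np.array([d.x_px for d in self.detections])

    @property
    def y_px(self) -> np.ndarray:
        return np.array([d.y_px for d in self.detections])

    @property
    def s_nm(self) -> np.ndarray:
        return np.array([d.s_nm for d in self.detections])

    @property
    def t_s(self) -> np.ndarray:
        if self._t_s is None:
            return self.frames.astype(float)
        return self._t_s

    _t_s: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def set_times(self, frame_interval_s: float) -> None:
        self._t_s = self.frames * frame_interval_s

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def span_frames(self) -> int:
        f = self.frames
        return int(f[-1] - f[0] + 1)

    def duration_s(self, frame_interval_s: float) -> float:
        return self.span_frames * frame_interval_s

    @property
    def net_displacement_nm(self) -> float:
        s = self.s_nm
        s = s[np.isfinite(s)]
        return float(s[-1] - s[0]) if s.size >= 2 else 0.0


def link_trajectories(
    detections: list[Detection],
    max_disp_nm: float = 650.0,
    max_gap: int = 2,
    pixel_size_nm: float = 162.5,
) -> list[Trajectory]:
    """Greedy frame-to-frame nearest-neighbor linking with gap bridging.

    Links cost their Euclidean displacement and are rejected beyond
    ``max_disp_nm`` regardless of the gap length; a track may bridge up
    to ``max_gap`` consecutive missing frames (blinking).  Assignment is
    deterministic: candidate links are consumed in order of (distance,
    detection index).  Unlinked detections become length-1 tracks.
    """
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    for frame_dets in by_frame.values():
        frame_dets.sort(key=lambda d: d.index)

    active: list[list[Detection]] = []
    finished: list[list[Detection]] = []
    for frame in sorted(by_frame):
        dets = by_frame[frame]
        # drop tracks that can no longer be extended
        still = []
        for tr in active:
            if frame - tr[-1].frame > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        candidates = []
        for ti, tr in enumerate(active):
            last = tr[-1]
            limit_px = max_disp_nm / pixel_size_nm
            for det in dets:
                dist = float(np.hypot(det.x_px - last.x_px, det.y_px - last.y_px))
                if dist <= limit_px:
                    candidates.append((dist, det.index, ti, det))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, det_idx, ti, det in candidates:
            if ti in used_tracks or det_idx in used_dets:
                continue
            active[ti].append(det)
            used_tracks.add(ti)
            used_dets.add(det_idx)
        for det in dets:
            if det.index not in used_dets:
                active.append([det])
    finished.extend(active)
    finished.sort(key=lambda tr: (tr[0].frame, tr[0].index))
    return [Trajectory(track_id=i, detections=tr) for i, tr in enumerate(finished)]


def project_onto_axis(
    trajectory: Trajectory, axis: AxisPolyline, off_axis_factor: float = 3.0
) -> Trajectory:
    """Assign each detection its arc-length coordinate s (nm, tip-ward).

    Detections farther than ``off_axis_factor * line_width`` px from the
    axis are flagged ``off_axis`` and their s stays NaN.
    """
    limit_px = off_axis_factor * axis.line_width_px
    for det in trajectory.detections:
        s_nm, dist_px = axis.project(det.x_px, det.y_px)
        if dist_px > limit_px:
            det.flags.add("off_axis")
            det.s_nm = np.nan
        else:
            det.s_nm = s_nm
    return trajectory


@dataclass
class ClassifierConfig:
    """Decision parameters of the trajectory classifier."""

    transient_max_frames: int = 1
    k_static: float = 3.0
    bic_penalty: float = 1.0
    min_step_factor: float = 2.0  # minimum detectable step, in localization SDs
    psf_sigma_nm: float | None = None  # enables the motion-blur width gate
    blur_sigma_factor: float = 1.2


def classify_trajectory(
    trajectory: Trajectory,
    localization_sd_nm: float,
    frame_interval_s: float = 1.0,
    config: ClassifierConfig | None = None,
) -> str:
    """Assign a motion class to a projected trajectory.

    Rules in order: *transient* when the observed span is at most
    ``transient_max_frames`` frames, or (when the PSF width is supplied)
    when the median fitted spot width exceeds ``blur_sigma_factor``
    times the PSF sigma — motion blur marks a molecule diffusing faster
    than the exposure can freeze; *static* when the net along-axis
    displacement (taken from the OLS trend, which is robust to endpoint
    noise) is below ``k_static * sigma_loc * sqrt(2)``; otherwise
    constant, linear and
    staircase models of s(t) compete by BIC — a winning positive-slope
    line is *processive*, a winning staircase with >= 2 plateaus is
    *stepwise*, a winning constant is *static*, anything else is
    *unclassified*.
    """
    if config is None:
        config = ClassifierConfig()
    if trajectory.span_frames <= config.transient_max_frames:
        trajectory.motion_class = "transient"
        return trajectory.motion_class
    s = trajectory.s_nm
    t = trajectory.frames * frame_interval_s
    keep = np.isfinite(s)
    if config.psf_sigma_nm is not None:
        # a molecule moving fast within the exposure fits wider than the
        # PSF; stationary emitters (including steppers between steps and
        # slow processive motors) fit at the PSF width
        widths = np.array([d.fit_sigma_nm for d in trajectory.detections])
        wide = widths > config.blur_sigma_factor * config.psf_sigma_nm
        if wide.any() and np.median(widths[widths > 0]) > (
            config.blur_sigma_factor * config.psf_sigma_nm
        ):
            trajectory.motion_class = "transient"
            return trajectory.motion_class
        # minority wide detections are blur from a molecule passing
        # through the link radius, not the tracked emitter: exclude them
        if wide.any() and (~wide).sum() >= 3:
            keep = keep & ~wide
    s, t = s[keep], t[keep]
    s, t = _trim_terminal_outliers(s, t, localization_sd_nm)
    n = s.size
    if n <= config.transient_max_frames:
        trajectory.motion_class = "transient"
        return trajectory.motion_class
    # net displacement evidence: endpoint difference and OLS trend must
    # both be small (either alone is fooled by endpoint noise or by
    # non-monotonic contamination)
    endpoint = abs(s[-1] - s[0])
    if n >= 3:
        trend = abs(estimate_velocity(s, t).velocity_nm_s * (t[-1] - t[0]))
    else:
        trend = endpoint
    if max(endpoint, trend) < config.k_static * localization_sd_nm * np.sqrt(2.0):
        trajectory.motion_class = "static"
        return trajectory.motion_class
    if n < 5:
        # too short for the staircase model: constant vs linear only
        trajectory.motion_class = _short_track_class(s, t, config)
        return trajectory.motion_class

    penalty = config.bic_penalty
    logn = np.log(n)
    rss_const = float(((s - s.mean()) ** 2).sum())
    bic_const = n * np.log(max(rss_const, 1e-12 * n) / n) + penalty * 1 * logn

    vel = estimate_velocity(s, t)
    resid = s - (s.mean() + vel.velocity_nm_s * (t - t.mean()))
    rss_lin = float((resid**2).sum())
    bic_lin = n * np.log(max(rss_lin, 1e-12 * n) / n) + penalty * 2 * logn

    step_fit = fit_steps(
        s,
        t,
        penalty=penalty,
        min_step_nm=config.min_step_factor * localization_sd_nm,
    )
    bic_step = step_fit.bic

    bics = {"static": bic_const, "linear": bic_lin, "stepwise": bic_step}
    winner = min(bics, key=lambda k: (bics[k], _MODEL_ORDER[k]))
    if winner == "linear":
        trajectory.motion_class = (
            "processive" if vel.velocity_nm_s > 0 else "unclassified"
        )
    elif winner == "stepwise":
        if step_fit.n_plateaus >= 2:
            trajectory.motion_class = "stepwise"
        else:
            trajectory.motion_class = "static"
    else:
        trajectory.motion_class = "static"
    return trajectory.motion_class


_MODEL_ORDER = {"static": 0, "linear": 1, "stepwise": 2}


def _trim_terminal_outliers(
    s: np.ndarray,
    t: np.ndarray,
    loc_sd_nm: float,
    k: float = 5.0,
    min_jump_nm: float = 250.0,
    max_trim: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop isolated contaminated detections at the track ends.

    The link made just before a molecule disappears (or just after it
    appears) sometimes grabs a nearby spurious or passing detection.
    An end point is discarded (at most ``max_trim`` per end) when it is
    isolated — it disagrees with both the local median and its
    immediate neighbor — and its jump exceeds both ``k`` track-noise
    SDs and ``min_jump_nm``.  The jump floor sits above any single
    motor step (100-200 nm), so a genuine final step survives while a
    several-hundred-nm grab is removed.
    """
    if s.size >= 5:
        diffs = np.abs(np.diff(s))
        noise = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)
        noise = max(noise, 0.25 * loc_sd_nm)
    else:
        noise = loc_sd_nm
    thr = max(k * noise, min_jump_nm)
    for _ in range(max_trim):
        if s.size < 5:
            break
        if (
            abs(s[0] - np.median(s[:4])) > thr
            and abs(s[0] - s[1]) > thr
        ):
            s, t = s[1:], t[1:]
            continue
        break
    for _ in range(max_trim):
        if s.size < 5:
            break
        if (
            abs(s[-1] - np.median(s[-4:])) > thr
            and abs(s[-1] - s[-2]) > thr
        ):
            s, t = s[:-1], t[:-1]
            continue
        break
    return s, t


def _short_track_class(s: np.ndarray, t: np.ndarray, config: ClassifierConfig) -> str:
    n = s.size
    if n < 3:
        return "unclassified"
    logn = np.log(n)
    rss_const = float(((s - s.mean()) ** 2).sum())
    vel = estimate_velocity(s, t)
    resid = s - (s.mean() + vel.velocity_nm_s * (t - t.mean()))
    rss_lin = float((resid**2).sum())
    bic_const = n * np.log(max(rss_const, 1e-12 * n) / n) + config.bic_penalty * logn
    bic_lin = n * np.log(max(rss_lin, 1e-12 * n) / n) + config.bic_penalty * 2 * logn
    if bic_lin < bic_const and vel.velocity_nm_s > 0:
        return "processive"
    return "static"


def trajectories_to_frame(
    trajectories: list[Trajectory], frame_interval_s: float = 1.0
) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for det in tr.detections:
            rows.append(
                (
                    tr.track_id,
                    det.frame,
                    det.x_px,
                    det.y_px,
                    det.s_nm,
                    det.sum_intensity,
                    tr.motion_class,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "x_px", "y_px", "s_nm", "sum_intensity", "class"],
    )
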