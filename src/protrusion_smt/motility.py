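"""Velocity and step statistics for along-axis trajectories.

Velocity is the ordinary least-squares slope of the along-axis position
s(t); population summaries report mean +/- sample SD over processive
tracks.  Step detection fits a piecewise-constant ("staircase") model by
greedy binary segmentation: the changepoint that maximally reduces the
residual sum of squares is added while the Bayesian information
criterion keeps improving.  Plateau means define signed step sizes
(tip-ward positive; retrograde steps keep their negative sign) and
plateau durations define dwell times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VelocityEstimate:
    velocity_nm_s: float
    stderr_nm_s: float
    n_points: int


@dataclass
class VelocitySummary:
    """Population velocity statistics over qualifying trajectories."""

    velocities_nm_s: np.ndarray
    mean_nm_s: float
    sd_nm_s: float
    n: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    sd_undefined: bool = False  # n < 2: SD reported as 0 with this flag

    def to_dict(self) -> dict:
        return {
            "mean_nm_s": self.mean_nm_s,
            "sd_nm_s": self.sd_nm_s,
            "n": self.n,
            "sd_undefined": self.sd_undefined,
        }


@dataclass
class StepEvent:
    """One discrete displacement between two stationary plateaus."""

    time_s: float
    size_nm: float  # signed, tip-ward positive
    dwell_s: float  # duration of the preceding plateau
    track_id: int = -1


@dataclass
class StepFit:
    """Full result of the piecewise-constant trajectory fit."""

    events: list[StepEvent]
    boundaries: np.ndarray  # indices where a new plateau starts
    plateau_means: np.ndarray
    rss: float
    bic: float
    n_points: int
    ramp_like: bool = False  # many ~1-frame uniform steps: really a ramp

    @property
    def n_plateaus(self) -> int:
        return len(self.plateau_means)


def estimate_velocity(
    s_series: np.ndarray, t_series: np.ndarray
) -> VelocityEstimate:
    """OLS slope of s (nm) against t (s), with its standard error."""
    s = np.asarray(s_series, dtype=float)
    t = np.asarray(t_series, dtype=float)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("s and t must be 1-D arrays of equal length")
    n = s.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    tbar = t.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0:
        raise ValueError("all time points identical")
    slope = float(((t - tbar) * (s - s.mean())).sum() / sxx)
    resid = s - (s.mean() + slope * (t - tbar))
    rss = float((resid**2).sum())
    stderr = float(np.sqrt(max(rss, 0.0) / (n - 2) / sxx))
    return VelocityEstimate(velocity_nm_s=slope, stderr_nm_s=stderr, n_points=n)


def summarize_velocities(
    trajectories,
    class_filter: set[str] | None = None,
    bin_width_nm_s: float = 25.0,
) -> VelocitySummary:
    """Velocity summary over trajectories passing the class filter.

    ``trajectories`` is an iterable of objects with ``s_nm``, ``t_s``
    and ``motion_class`` attributes (or (s, t) tuples when
    ``class_filter`` is None).  Zero qualifying tracks yields an empty
    summary with n = 0, not an error.
    """
    if class_filter is None:
        class_filter = {"processive"}
    velocities = []
    for traj in trajectories:
        if hasattr(traj, "motion_class"):
            if class_filter and traj.motion_class not in class_filter:
                continue
            s, t = traj.s_nm, traj.t_s
        else:
            s, t = traj
        s = np.asarray(s, float)
        keep = np.isfinite(s)
        if keep.sum() < 3:
            continue
        velocities.append(
            estimate_velocity(s[keep], np.asarray(t, float)[keep]).velocity_nm_s
        )
    v = np.asarray(velocities, dtype=float)
    if v.size == 0:
        return VelocitySummary(
            velocities_nm_s=v,
            mean_nm_s=np.nan,
            sd_nm_s=np.nan,
            n=0,
            hist_edges=np.array([]),
            hist_counts=np.array([]),
        )
    mean = float(v.mean())
    sd_undefined = v.size < 2
    sd = 0.0 if sd_undefined else float(v.std(ddof=1))
    lo = np.floor(v.min() / bin_width_nm_s) * bin_width_nm_s
    hi = np.ceil(v.max() / bin_width_nm_s) * bin_width_nm_s
    if hi <= lo:
        hi = lo + bin_width_nm_s
    edges = np.arange(lo, hi + bin_width_nm_s / 2, bin_width_nm_s)
    counts, edges = np.histogram(v, bins=edges)
    return VelocitySummary(
        velocities_nm_s=v,
        mean_nm_s=mean,
        sd_nm_s=sd,
        n=int(v.size),
        hist_edges=edges,
        hist_counts=counts,
        sd_undefined=sd_undefined,
    )


def _segment_rss(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """RSS of the constant fit to x[i:j] via prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return max(s2 - s * s / n, 0.0)


def fit_piecewise_constant(
    s_series: np.ndarray,
    penalty: float = 1.0,
    min_size: int = 1,
    max_plateaus: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy binary-segmentation staircase fit.

    Repeatedly adds the changepoint with the largest RSS reduction while
    the BIC improves.  The criterion is
    ``n ln(RSS/n) + penalty * (1 + 3(m-1)) * ln n`` for m plateaus: each
    plateau past the first contributes its mean plus a double-weighted
    changepoint-location term, following the modified BIC for
    changepoint problems (the location is optimized over n candidate
    positions, so it costs more than an ordinary parameter).
    Returns (plateau start indices, plateau means, RSS).
    """
    x = np.asarray(s_series, dtype=float)
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x**2)])
    boundaries = [0, n]
    rss = _segment_rss(prefix, prefix2, 0, n)

    def bic(total_rss: float, m: int) -> float:
        eff = max(total_rss, 1e-12 * max(n, 1))
        return n * np.log(eff / n) + penalty * (1 + 3 * (m - 1)) * np.log(n)

    current_bic = bic(rss, 1)
    while max_plateaus is None or len(boundaries) - 1 < max_plateaus:
        best_gain, best_split = 0.0, None
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if b - a < 2 * min_size:
                continue
            base = _segment_rss(prefix, prefix2, a, b)
            for c in range(a + min_size, b - min_size + 1):
                gain = base - (
                    _segment_rss(prefix, prefix2, a, c)
                    + _segment_rss(prefix, prefix2, c, b)
                )
                if gain > best_gain:
                    best_gain, best_split = gain, c
        if best_split is None:
            break
        new_rss = rss - best_gain
        new_bic = bic(new_rss, len(boundaries))
        if new_bic >= current_bic:
            break
        boundaries = sorted(boundaries + [best_split])
        rss, current_bic = new_rss, new_bic
    starts = np.asarray(boundaries[:-1], dtype=int)
    ends = np.asarray(boundaries[1:], dtype=int)
    means = np.array([x[a:b].mean() for a, b in zip(starts, ends)])
    return starts, means, rss


def _merge_small_steps(
    x: np.ndarray, starts: np.ndarray, means: np.ndarray, min_step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent plateaus whose mean difference is below min_step."""
    starts = list(starts)
    while len(starts) > 1:
        ends = starts[1:] + [len(x)]
        means = [x[a:b].mean() for a, b in zip(starts, ends)]
        diffs = np.abs(np.diff(means))
        i = int(np.argmin(diffs))
        if diffs[i] >= min_step:
            break
        del starts[i + 1]
    ends = starts[1:] + [len(x)]
    means = np.array([x[a:b].mean() for a, b in zip(starts, ends)])
    return np.asarray(starts, dtype=int), means


def fit_steps(
    s_series: np.ndarray,
    t_series: np.ndarray,
    penalty: float = 1.0,
    min_step_nm: float = 0.0,
    track_id: int = -1,
) -> StepFit:
    """Fit the staircase model and extract step events.

    A fit with more than 5 steps whose median dwell is at most two frame
    intervals is flagged ``ramp_like``: a continuous ramp masquerading
    as a staircase.
    """
    s = np.asarray(s_series, dtype=float)
    t = np.asarray(t_series, dtype=float)
    if s.size < 5:
        raise ValueError(f"need at least 5 points, got {s.size}")
    starts, means, rss = fit_piecewise_constant(s, penalty=penalty)
    if min_step_nm > 0 and len(starts) > 1:
        starts, means = _merge_small_steps(s, starts, means, min_step_nm)
        ends = np.concatenate([starts[1:], [s.size]])
        rss = float(
            sum(((s[a:b] - m) ** 2).sum() for a, b, m in zip(starts, ends, means))
        )
    n = s.size
    m = len(starts)
    bic = n * np.log(max(rss, 1e-12 * n) / n) + penalty * (1 + 3 * (m - 1)) * np.log(n)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    events = []
    for i in range(1, m):
        idx = starts[i]
        prev_start = starts[i - 1]
        events.append(
            StepEvent(
                time_s=float(t[idx]),
                size_nm=float(means[i] - means[i - 1]),
                dwell_s=float(t[idx] - t[prev_start]) if idx > prev_start else dt,
                track_id=track_id,
            )
        )
    dwell_frames = [ev.dwell_s / dt for ev in events]
    ramp_like = len(events) > 5 and np.median(dwell_frames) <= 2.0
    return StepFit(
        events=events,
        boundaries=starts,
        plateau_means=means,
        rss=float(rss),
        bic=float(bic),
        n_points=n,
        ramp_like=ramp_like,
    )


def detect_steps(
    s_series: np.ndarray,
    t_series: np.ndarray,
    penalty: float = 1.0,
    min_step_nm: float = 0.0,
    track_id: int = -1,
) -> list[StepEvent]:
    """Step events of one trajectory (see :func:`fit_steps`)."""
    return fit_steps(
        s_series, t_series, penalty=penalty, min_step_nm=min_step_nm,
        track_id=track_id,
    ).events


def is_undersampled(
    velocity_nm_s: float, frame_interval_s: float, max_disp_nm: float = 650.0
) -> bool:
    """True when a molecule at this velocity outruns the linking radius.

    A motor moving ``velocity_nm_s`` covers more than ``max_disp_nm``
    between consecutive frames when sampled too slowly (e.g. a 2 um/s
    motor at 1-s intervals), so its detections cannot be linked and any
    recovered track underestimates the velocity; such data needs a
    shorter frame interval.
    """
    return abs(velocity_nm_s) * frame_interval_s > max_disp_nm


@dataclass
class StepStatistics:
    mean_size_nm: float
    sd_size_nm: float
    mean_dwell_s: float
    n: int
    sd_undefined: bool = False


def step_statistics(events: list[StepEvent]) -> StepStatistics:
    """Sample statistics of step sizes and dwells; n = 0 allowed."""
    if not events:
        return StepStatistics(np.nan, np.nan, np.nan, 0)
    sizes = np.array([e.size_nm for e in events])
    dwells = np.array([e.dwell_s for e in events])
    sd_undefined = sizes.size < 2
    return StepStatistics(
        mean_size_nm=float(sizes.mean()),
        sd_size_nm=0.0 if sd_undefined else float(sizes.std(ddof=1)),
        mean_dwell_s=float(dwells.mean()),
        n=int(sizes.size),
        sd_undefined=sd_undefined,
    )


def steps_to_frame(events: list[StepEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": [e.track_id for e in events],
            "t_s": [e.time_s for e in events],
            "size_nm": [e.size_nm for e in events],
            "dwell_s": [e.dwell_s for e in events],
        }
    )
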