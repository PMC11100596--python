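"""Synthetic single-molecule movie generator with exact ground truth.

Molecules live on a straight protrusion axis and belong to one of four
motion classes observed for myosins and control constructs in F-actin
protrusions:

* ``static``     — bound to the F-actin core, fixed position.
* ``diffusive``  — free diffusion along the protrusion (reflected at the
  base and tip); with realistic D the molecule moves much farther than
  the PSF within one frame, so it blurs out and is detectable for at
  most about one frame.
* ``processive`` — continuous tip-ward translocation at a velocity drawn
  from a normal truncated at zero (~100 +/- 50 nm/s for motor dimers).
* ``stepper``    — staircase motion: exponential dwells interrupted by
  discrete tip-ward jumps of 100-200 nm.

Each molecule carries one or two fluorophores whose emission undergoes
irreversible photobleaching (exponential lifetime) and reversible
blinking (two-state Markov chain per frame).  Rendering follows the
standard camera model: pixel-integrated Gaussian PSF, Poisson shot
noise on photons plus background, linear gain, additive Gaussian read
noise.  A deterministic render mode replaces sampling by expectations
for exact photometric tests.

Randomness is reproducible: every molecule draws from its own
``numpy.random.Generator`` sub-stream derived from the config seed and
the molecule id, so tracks are stable under reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from protrusion_smt.config import MOTION_CLASSES, ConfigError, SimConfig
from protrusion_smt.io import Movie

N_DIFFUSION_SUBSTEPS = 10


@dataclass
class GroundTruthTrack:
    """True state of one simulated molecule over the whole movie."""

    molecule_id: int
    motion_class: str
    s_nm: np.ndarray  # (n_frames,) along-axis position
    active: np.ndarray  # (n_fluor, n_frames) bool emission state
    fluor_brightness: np.ndarray  # (n_fluor,) relative brightness, mean 1
    velocity_nm_s: float | None = None  # processive only
    step_times_s: np.ndarray | None = None  # stepper only
    step_sizes_nm: np.ndarray | None = None
    s_sub_nm: np.ndarray | None = None  # (n_frames, n_sub) diffusive only
    birth_frame: int = 0
    death_frame: int | None = None  # first frame with all fluorophores bleached

    @property
    def n_active(self) -> np.ndarray:
        """Active fluorophore count per frame."""
        return self.active.sum(axis=0)

    def xy_px(self, config: SimConfig) -> np.ndarray:
        """Map along-axis positions to pixel coordinates, rows (x, y)."""
        return _s_to_xy(self.s_nm, config)

    def xy_sub_px(self, config: SimConfig) -> np.ndarray | None:
        """Sub-frame pixel positions (n_frames, n_sub, 2), diffusive only."""
        if self.s_sub_nm is None:
            return None
        return _s_to_xy(self.s_sub_nm, config)


def _s_to_xy(s_nm: np.ndarray, config: SimConfig) -> np.ndarray:
    p0, p1 = config.axis_endpoints_px
    u = (p1 - p0) / np.hypot(*(p1 - p0))
    s_px = np.asarray(s_nm, dtype=float) / config.pixel_size
    return p0[None, :] + s_px[..., None] * u[None, :]


def _molecule_rng(seed: int, molecule_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(molecule_id)]))


def _sample_photophysics(
    config: SimConfig, rng: np.random.Generator, n_fluor: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fluorophore emission mask (n_fluor, n_frames) and brightness."""
    if n_fluor is None:
        n_fluor = config.fluorophores_per_molecule
    dt = config.frame_interval
    n = config.n_frames
    p_off = -np.expm1(-config.blink_off_rate * dt)
    p_on = -np.expm1(-config.blink_on_rate * dt)
    active = np.zeros((n_fluor, n), dtype=bool)
    for j in range(n_fluor):
        bleach_t = (
            rng.exponential(1.0 / config.bleach_rate)
            if config.bleach_rate > 0
            else np.inf
        )
        on = True
        for t in range(n):
            if t * dt >= bleach_t:
                break  # bleached: dark forever
            active[j, t] = on
            if on:
                if rng.random() < p_off:
                    on = False
            else:
                if rng.random() < p_on:
                    on = True
    brightness = np.abs(
        rng.normal(1.0, config.brightness_cv, size=n_fluor)
    )  # relative, truncated away from negative
    return active, brightness


def _simulate_motion(
    config: SimConfig, motion_class: str, rng: np.random.Generator
) -> dict:
    n = config.n_frames
    dt = config.frame_interval
    length = config.length_nm
    out: dict = {"s_sub_nm": None, "velocity_nm_s": None}

    if motion_class == "static":
        s0 = rng.uniform(0, length)
        out["s_nm"] = np.full(n, s0)

    elif motion_class == "diffusive":
        # sub-steps cover the exposure window (motion blur); one coarse
        # step bridges the dark remainder of the frame interval
        s0 = rng.uniform(0, length)
        n_sub = N_DIFFUSION_SUBSTEPS
        d_nm2 = config.diffusion_coeff * 1e6  # nm^2/s
        sigma_sub = np.sqrt(2.0 * d_nm2 * config.exposure / n_sub)
        gap = max(dt - config.exposure, 0.0)
        sigma_gap = np.sqrt(2.0 * d_nm2 * gap)
        s_sub = np.empty((n, n_sub))
        pos = s0
        for t in range(n):
            for j in range(n_sub):
                pos += rng.normal(0.0, sigma_sub)
                s_sub[t, j] = pos
            if sigma_gap > 0:
                pos += rng.normal(0.0, sigma_gap)
        s_sub = _reflect(s_sub, 0.0, length)
        out["s_nm"] = s_sub.mean(axis=1)  # exposure-window centroid
        out["s_sub_nm"] = s_sub

    elif motion_class == "processive":
        if config.velocity_sd > 0:
            a = -config.velocity_mean / config.velocity_sd
            v = float(
                stats.truncnorm.rvs(
                    a, np.inf, loc=config.velocity_mean,
                    scale=config.velocity_sd, random_state=rng,
                )
            )
        else:
            v = config.velocity_mean
        travel = v * (n - 1) * dt
        s0 = rng.uniform(0, max(length - travel, 1e-9)) if travel < length else 0.0
        s = s0 + v * dt * np.arange(n)
        out["s_nm"] = np.minimum(s, length)
        out["velocity_nm_s"] = v

    elif motion_class == "stepper":
        # leave room for the expected tip-ward travel over the movie
        if np.isfinite(config.step_dwell_mean):
            expected_travel = (
                (n - 1) * dt / config.step_dwell_mean
                * 0.5 * (config.step_size_low + config.step_size_high)
            )
        else:
            expected_travel = 0.0
        s0 = rng.uniform(0, max(length - expected_travel, length / 2))
        times, sizes = [], []
        s = np.full(n, s0)
        if np.isfinite(config.step_dwell_mean):
            t = rng.exponential(config.step_dwell_mean)
            pos = s0
            horizon = (n - 1) * dt
            while t <= horizon:
                size = rng.uniform(config.step_size_low, config.step_size_high)
                pos = min(pos + size, length)
                first = int(np.ceil(t / dt))
                s[first:] = pos
                times.append(t)
                sizes.append(size)
                t += rng.exponential(config.step_dwell_mean)
        out["s_nm"] = s
        out["step_times_s"] = np.asarray(times)
        out["step_sizes_nm"] = np.asarray(sizes)

    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown motion class {motion_class!r}")
    return out


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect a path into [lo, hi] (billiard boundary conditions)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def simulate_tracks(config: SimConfig) -> list[GroundTruthTrack]:
    """Draw ground-truth tracks for every molecule in the config.

    Class labels are multinomial with ``motion_mix``; all per-molecule
    randomness comes from a sub-stream keyed by the molecule id.
    """
    config.validate()
    master = np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed), 0xC1A55])
    )
    classes = master.choice(
        MOTION_CLASSES,
        size=config.n_molecules,
        p=[config.motion_mix.get(c, 0.0) for c in MOTION_CLASSES],
    )
    tracks = []
    for mid, motion_class in enumerate(classes):
        rng = _molecule_rng(config.rng_seed, mid)
        motion = _simulate_motion(config, str(motion_class), rng)
        active, brightness = _sample_photophysics(
            config, rng, config.n_fluorophores(str(motion_class))
        )
        ever = active.any(axis=0)
        death = None
        alive_any = np.where(ever)[0]
        if alive_any.size:
            # death = first frame after which emission never returns
            death = int(alive_any[-1]) + 1
            if death >= config.n_frames:
                death = None
        else:
            death = 0
        tracks.append(
            GroundTruthTrack(
                molecule_id=mid,
                motion_class=str(motion_class),
                s_nm=motion["s_nm"],
                active=active,
                fluor_brightness=brightness,
                velocity_nm_s=motion.get("velocity_nm_s"),
                step_times_s=motion.get("step_times_s"),
                step_sizes_nm=motion.get("step_sizes_nm"),
                s_sub_nm=motion.get("s_sub_nm"),
                birth_frame=0,
                death_frame=death,
            )
        )
    return tracks


def _gaussian_patch(
    shape: tuple[int, int], x: float, y: float, sigma_px: float, photons: float
) -> tuple[slice, slice, np.ndarray]:
    """Pixel-integrated isotropic Gaussian restricted to a local patch.

    Pixel centers sit at integer coordinates; the value of pixel (i, j)
    is the Gaussian mass inside [j-1/2, j+1/2] x [i-1/2, i+1/2], so the
    patch sums to ``photons`` up to the mass outside +/-5 sigma.
    """
    h, w = shape
    r = int(np.ceil(5 * sigma_px)) + 1
    y0, y1 = max(0, int(np.floor(y)) - r), min(h, int(np.ceil(y)) + r + 1)
    x0, x1 = max(0, int(np.floor(x)) - r), min(w, int(np.ceil(x)) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    denom = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (
        special.erf((xs + 0.5 - x) / denom) - special.erf((xs - 0.5 - x) / denom)
    )
    fy = 0.5 * (
        special.erf((ys + 0.5 - y) / denom) - special.erf((ys - 0.5 - y) / denom)
    )
    return slice(y0, y1), slice(x0, x1), photons * np.outer(fy, fx)


def render_movie(
    tracks: list[GroundTruthTrack],
    config: SimConfig,
    deterministic: bool = False,
) -> Movie:
    """Render tracks into a calibrated camera movie.

    ``deterministic=True`` returns the expected image (no Poisson or
    read noise) for exact photometric tests; pixel values are then the
    expectation in ADU.  Diffusive molecules are integrated over
    sub-frame positions to produce motion blur.
    """
    config.validate()
    h, w = config.image_shape
    sigma_px = config.psf_sigma / config.pixel_size
    drift_px = (
        config.drift_model.displacement_nm(np.arange(config.n_frames))
        / config.pixel_size
    )
    _check_axis_in_field(config, drift_px)
    for tr in tracks:
        if tr.s_nm.shape[0] != config.n_frames:
            raise ConfigError(
                f"track {tr.molecule_id} has {tr.s_nm.shape[0]} frames, "
                f"config expects {config.n_frames}"
            )

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed), 0xCA11E7A])
    )
    frames = np.empty((config.n_frames, h, w), dtype=np.float64)
    for t in range(config.n_frames):
        photons = np.full((h, w), float(config.background))
        for tr in tracks:
            n_act_each = tr.active[:, t]
            if not n_act_each.any():
                continue
            total_rel = float(tr.fluor_brightness[n_act_each].sum())
            amp = config.quantal_brightness * total_rel
            if tr.motion_class == "diffusive" and tr.s_sub_nm is not None:
                # integrate the sub-positions spanning the exposure
                subs = tr.s_sub_nm[t]
                xy = _s_to_xy(subs, config) + drift_px[t][None, :]
                for x, y in xy:
                    ys, xs, patch = _gaussian_patch(
                        (h, w), x, y, sigma_px, amp / len(subs)
                    )
                    photons[ys, xs] += patch
            else:
                x, y = _s_to_xy(np.array([tr.s_nm[t]]), config)[0] + drift_px[t]
                ys, xs, patch = _gaussian_patch((h, w), x, y, sigma_px, amp)
                photons[ys, xs] += patch
        if deterministic:
            img = photons * config.camera_gain
        else:
            img = rng.poisson(photons).astype(np.float64) * config.camera_gain
            if config.read_noise_sd > 0:
                img += rng.normal(0.0, config.read_noise_sd, size=img.shape)
        frames[t] = np.clip(img, 0.0, None)
    return Movie(
        data=frames,
        pixel_size_nm=config.pixel_size,
        frame_interval_s=config.frame_interval,
        meta={"deterministic": deterministic, "rng_seed": config.rng_seed},
    )


def _check_axis_in_field(config: SimConfig, drift_px: np.ndarray) -> None:
    h, w = config.image_shape
    ends = config.axis_endpoints_px  # (2, 2) rows (x, y)
    for t in range(drift_px.shape[0]):
        pts = ends + drift_px[t][None, :]
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
        )
        if not inside.any():
            raise ConfigError(
                f"drift pushes the protrusion axis fully outside the field "
                f"at frame {t}"
            )


# -- ground-truth persistence ---------------------------------------------

TRUTH_COLUMNS = [
    "molecule_id",
    "frame",
    "class",
    "s_nm",
    "x_px",
    "y_px",
    "n_active_fluor",
]


def tracks_to_frame_table(
    tracks: list[GroundTruthTrack], config: SimConfig
) -> pd.DataFrame:
    """Long-format per-frame table of the ground truth."""
    rows = []
    for tr in tracks:
        xy = tr.xy_px(config)
        n_act = tr.n_active
        for t in range(config.n_frames):
            rows.append(
                (
                    tr.molecule_id,
                    t,
                    tr.motion_class,
                    tr.s_nm[t],
                    xy[t, 0],
                    xy[t, 1],
                    int(n_act[t]),
                )
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_ground_truth(
    tracks: list[GroundTruthTrack], config: SimConfig, path: str | Path
) -> None:
    tracks_to_frame_table(tracks, config).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
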