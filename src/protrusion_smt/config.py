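"""Run and simulation configuration objects.

Defaults encode the imaging regime of the motivating experiments:
0.8-NA/40x detection (Gaussian PSF sigma ~152 nm), 162.5 nm pixels
(6.5 um sCMOS pixel / 40x), 100 ms exposures, 1-s frame intervals,
protrusions up to 10 um long, sparse labeling with one or two
fluorophores per molecule, processive velocities ~100 +/- 50 nm/s and
discrete steps of 100-200 nm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

MOTION_CLASSES = ("static", "diffusive", "processive", "stepper")


@dataclass
class DriftModel:
    """Parametric lateral sample drift: linear trend plus a sinusoid.

    Displacements are in nm of sample motion per frame index; both axes
    share the sinusoid period and phase.
    """

    linear_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    sine_amplitude_nm: tuple[float, float] = (0.0, 0.0)
    sine_period_frames: float = 25.0
    sine_phase_rad: float = 0.0

    def displacement_nm(self, frame: int | np.ndarray) -> np.ndarray:
        """Drift (dx_nm, dy_nm) at integer frame index (0 at frame 0)."""
        t = np.asarray(frame, dtype=float)
        phase = 2.0 * np.pi * t / self.sine_period_frames + self.sine_phase_rad
        dx = self.linear_nm_per_frame[0] * t + self.sine_amplitude_nm[0] * (
            np.sin(phase) - np.sin(self.sine_phase_rad)
        )
        dy = self.linear_nm_per_frame[1] * t + self.sine_amplitude_nm[1] * (
            np.sin(phase) - np.sin(self.sine_phase_rad)
        )
        return np.stack([dx, dy], axis=-1)

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.linear_nm_per_frame) and all(
            v == 0 for v in self.sine_amplitude_nm
        )


class ConfigError(ValueError):
    """Invalid configuration value or combination."""


@dataclass
class SimConfig:
    """Parameters of the synthetic single-molecule movie generator.

    Units: axis endpoints and protrusion length in um; pixel size, PSF
    sigma, step sizes and velocities in nm; times in s; brightness in
    photons per frame per active fluorophore at the configured exposure
    (rescaling the exposure rescales the expected photon count linearly).
    """

    axis_endpoints: tuple[tuple[float, float], tuple[float, float]] = (
        (2.0, 5.2),
        (12.0, 5.2),
    )
    protrusion_length: float = 10.0
    image_shape: tuple[int, int] = (64, 96)  # (rows, cols)
    pixel_size: float = 162.5
    frame_interval: float = 1.0
    exposure: float = 0.1
    n_frames: int = 50
    n_molecules: int = 10
    psf_sigma: float = 152.0
    quantal_brightness: float = 1000.0
    brightness_cv: float = 0.3
    background: float = 50.0
    read_noise_sd: float = 2.0
    camera_gain: float = 1.0
    bleach_rate: float = 0.01
    blink_off_rate: float = 0.05
    blink_on_rate: float = 0.5
    motion_mix: dict[str, float] = field(
        default_factory=lambda: {
            "static": 0.25,
            "diffusive": 0.25,
            "processive": 0.25,
            "stepper": 0.25,
        }
    )
    diffusion_coeff: float = 8.0
    velocity_mean: float = 100.0
    velocity_sd: float = 50.0
    step_size_low: float = 100.0
    step_size_high: float = 200.0
    step_dwell_mean: float = 5.0
    fluorophores_per_molecule: int = 2
    fluorophores_by_class: dict[str, int] | None = None
    drift_model: DriftModel = field(default_factory=DriftModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry -------------------------------------------------
    @property
    def length_nm(self) -> float:
        return self.protrusion_length * 1000.0

    def n_fluorophores(self, motion_class: str) -> int:
        """Fluorophores per molecule of the given class.

        A per-class override mirrors real labeling stoichiometry: only
        the homodimerized motor carries two tags; monomeric controls
        and heterodimerized (tethered) constructs carry one.
        """
        if self.fluorophores_by_class is not None:
            return self.fluorophores_by_class.get(
                motion_class, self.fluorophores_per_molecule
            )
        return self.fluorophores_per_molecule

    @property
    def axis_endpoints_px(self) -> np.ndarray:
        """Axis endpoints in pixel coordinates, rows of (x, y)."""
        return np.asarray(self.axis_endpoints, dtype=float) * 1000.0 / self.pixel_size

    def validate(self) -> None:
        positive = {
            "protrusion_length": self.protrusion_length,
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "exposure": self.exposure,
            "psf_sigma": self.psf_sigma,
            "quantal_brightness": self.quantal_brightness,
            "camera_gain": self.camera_gain,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{name} must be strictly positive, got {value!r}")
        nonneg = {
            "background": self.background,
            "read_noise_sd": self.read_noise_sd,
            "bleach_rate": self.bleach_rate,
            "blink_off_rate": self.blink_off_rate,
            "blink_on_rate": self.blink_on_rate,
            "brightness_cv": self.brightness_cv,
            "diffusion_coeff": self.diffusion_coeff,
            "velocity_sd": self.velocity_sd,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ConfigError(f"{name} must be non-negative, got {value!r}")
        if self.n_frames < 1 or self.n_molecules < 0:
            raise ConfigError("n_frames must be >=1 and n_molecules >=0")
        if self.fluorophores_per_molecule not in (1, 2):
            raise ConfigError("fluorophores_per_molecule must be 1 or 2")
        if self.fluorophores_by_class is not None:
            bad = set(self.fluorophores_by_class) - set(MOTION_CLASSES)
            if bad or any(
                v not in (1, 2) for v in self.fluorophores_by_class.values()
            ):
                raise ConfigError(
                    "fluorophores_by_class must map motion classes to 1 or 2"
                )
        if set(self.motion_mix) - set(MOTION_CLASSES):
            raise ConfigError(
                f"motion_mix keys must be a subset of {MOTION_CLASSES}"
            )
        total = sum(self.motion_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigError(f"motion_mix must sum to 1, sums to {total}")
        if any(v < 0 for v in self.motion_mix.values()):
            raise ConfigError("motion_mix proportions must be non-negative")
        if not 0 < self.step_size_low <= self.step_size_high:
            raise ConfigError("need 0 < step_size_low <= step_size_high")
        if not self.step_dwell_mean > 0:
            raise ConfigError("step_dwell_mean must be positive (may be inf)")
        p0, p1 = np.asarray(self.axis_endpoints, dtype=float)
        sep = float(np.hypot(*(p1 - p0)))
        if not np.isclose(sep, self.protrusion_length, rtol=1e-3):
            raise ConfigError(
                f"axis endpoint separation {sep:.4f} um inconsistent with "
                f"protrusion_length {self.protrusion_length} um"
            )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["drift_model"] = dataclasses.asdict(self.drift_model)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "drift_model" in d and isinstance(d["drift_model"], dict):
            dm = {
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in d["drift_model"].items()
            }
            d["drift_model"] = DriftModel(**dm)
        for key in ("axis_endpoints",):
            if key in d:
                d[key] = tuple(tuple(p) for p in d[key])
        for key in ("image_shape",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonify(self.to_dict())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """One end-to-end pipeline run: input, per-stage parameters, outputs.

    Exactly one of ``movie_path`` / ``sim`` must be set.  When ``sim`` is
    present the movie and its ground truth are generated first and the
    recovery report is produced at the end.
    """

    sim: SimConfig | None = None
    movie_path: str | None = None
    axis_csv: str | None = None
    out_dir: str = "run"
    seed: int = 0
    # stage switches / parameters
    correct_drift: bool = True
    reference_mode: str = "first"
    threshold_k: float = 5.0
    max_disp_nm: float = 650.0
    max_gap: int = 2
    line_width_px: int = 3
    reducer: str = "max"
    kymo_bin_nm: float | None = None
    bic_penalty: float = 1.0
    localization_sd_nm: float = 30.0
    max_match_dist_nm: float = 500.0
    deterministic_render: bool = False

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.movie_path is None):
            raise ConfigError("exactly one of sim / movie_path must be given")
        if self.sim is not None and isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict(self.sim)
        if self.movie_path is not None and self.axis_csv is None:
            raise ConfigError("axis_csv is required when loading a movie from disk")
        if self.reference_mode not in ("first", "sequential"):
            raise ConfigError("reference_mode must be 'first' or 'sequential'")
        if self.reducer not in ("max", "mean"):
            raise ConfigError("reducer must be 'max' or 'mean'")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonify(self.to_dict())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(_jsonify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonify(obj: Any) -> Any:
    """Recursively convert tuples/numpy scalars for YAML/JSON emission."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
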