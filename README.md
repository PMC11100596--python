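# protrusion-smt

Single-molecule tracking and kymograph analysis for time-lapse
fluorescence movies of organelles that protrude from the apical cell
surface — stereocilia of inner-ear hair cells, microvilli, filopodia.
It is built for the kind of experiment in which a motor protein (e.g.
MYO7A) is sparsely labeled with a bright dye, imaged in a single plane
every 0.1–1 s through a 0.8-NA/40× system, and its motion along the
protrusion's F-actin core is quantified from kymographs: lateral drift
correction, single-fluorophore spot photometry, trajectory linking,
motion classification and velocity/step statistics — plus a movie
simulator with exact ground truth so every stage can be validated.

## What it computes

**Drift correction.** Sample drift between frame *I_t* and the
reference is estimated by phase-only correlation: the cross-power
spectrum is normalized to unit modulus, *R = F_a F_b\* / |F_a F_b\*|*,
and its inverse transform peaks at the inter-frame shift. The integer
peak is refined to subpixel precision (parabolic fit or local DFT
upsampling) and polished by least-squares image matching — robust
Gauss–Newton minimization of Σ[*I_a*(p) − g·*I_b*(p+δ) − o]² over the
shift δ with gain/offset terms and Huber weights. Frames whose
correlation is weak, ambiguous or implies implausibly fast drift are
flagged; a movie with mostly unconfident frames is left uncorrected
rather than guessed at.

**Spot photometry.** Diffraction-limited puncta are detected by a
difference-of-Gaussians filter matched to the PSF (σ ≈ 0.21 λ/NA ≈
152 nm), thresholded at *k* robust noise SDs, and refined by 2-D
Gaussian fits. The summed intensity of a punctum is
Σ(aperture) − median(annulus)·*n*<sub>aperture</sub>. A 1-D Gaussian
mixture over summed intensities, with the order chosen by BIC,
separates the quantal populations: one-fluorophore puncta at the
quantal intensity *Q* and two-fluorophore (dimer-labeled) puncta at
≈ 2*Q*. Averaged line scans validate that puncta match the PSF of a
point source.

**Kymographs and trajectories.** A kymograph resamples each frame along
the protrusion axis (base → tip) into a distance × time map. Detections
are linked by deterministic greedy nearest-neighbor assignment with
blinking-gap bridging, projected to the arc-length coordinate *s(t)*,
and classified — static, transient (diffusing molecules visible ≈ one
frame), processive (continuous tip-ward ramp) or stepwise (staircase) —
by comparing constant, linear and piecewise-constant models of *s(t)*
under BIC.

**Motility statistics.** Velocity is the OLS slope of *s(t)* (the motor
population model is a normal truncated at zero, ~100 ± 50 nm/s for
processive dimers); steps are found by greedy binary segmentation with
a changepoint-penalized BIC, yielding signed 100–200 nm step sizes and
exponential dwells.

## Worked example

```python
from protrusion_smt.config import SimConfig, RunConfig
from protrusion_smt.pipeline import run_pipeline

config = RunConfig(
    sim=SimConfig(
        n_molecules=6,
        n_frames=50,
        motion_mix={"static": 0.3, "diffusive": 0.1,
                    "processive": 0.4, "stepper": 0.2},
    ),
    seed=42,
    out_dir="myo7a_run",
    correct_drift=False,   # no injected drift in this simulation
)
artifacts = run_pipeline(config)

summary = artifacts["velocity_summary"]
print(f"trajectories: {len(artifacts['trajectories'])}")
print(f"processive velocity: {summary.mean_nm_s:.0f} +/- "
      f"{summary.sd_nm_s:.0f} nm/s (n = {summary.n})")
report = artifacts["report"]
print(f"recall by true class: "
      f"{ {k: round(v, 2) for k, v in report.recall.items()} }")
```

prints

```
trajectories: 37
processive velocity: 91 +/- 41 nm/s (n = 4)
recall by true class: {'diffusive': 1.0, 'processive': 0.67, 'static': 1.0, 'stepper': 1.0}
```

The simulated processive motors draw velocities from the truncated
normal (mean 100, SD 50 nm/s), so the recovered population mean of
91 ± 41 nm/s over four tracks is the expected result at this sample
size; `myo7a_run/` now contains the movie, ground truth, drift trace,
detections, classified tracks, kymograph and a JSON recovery report.
The 37 trajectories exceed the 6 molecules because blinking splits
tracks and each brief appearance of the diffusing molecule is its own
one-frame track.

The same stages are available from the shell:

```bash
protrusion-smt simulate --config sim.yaml --out movie.tif --truth truth.csv --seed 42
protrusion-smt register --in movie.tif --out corrected.tif --trace drift.csv
protrusion-smt spots    --in corrected.tif --psf-sigma-nm 152 --out detections.csv
protrusion-smt kymo     --in corrected.tif --axis axis.csv --out kymo.tif
protrusion-smt track    --detections detections.csv --axis axis.csv --out tracks.csv
protrusion-smt motility --tracks tracks.csv --out summary.json
protrusion-smt run      --config run.yaml
```

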