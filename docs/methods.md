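# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
design decisions that were genuinely open.

## Imaging model and simulator

The simulator generates single-plane time-lapse movies of single
fluorophores inside a straight protrusion up to 10 μm long, under the
imaging regime the package targets: 0.8-NA/40× detection approximated
by an isotropic Gaussian PSF with σ = 0.21·λ/NA ≈ 152 nm at λ = 580 nm;
162.5 nm pixels (a 6.5 μm sCMOS pixel behind 40× magnification); 100 ms
exposures at frame intervals of 0.1–1 s (default 1 s); a camera model
of Poisson shot noise on photons plus background, linear gain, and
additive Gaussian read noise. Pixel values are pixel-integrated
Gaussian masses (difference of error functions), so photon counts are
conserved to the sub-percent truncation of the ±5σ rendering patch. A
deterministic render mode replaces all sampling by expectations for
exact photometric tests.

Molecules carry one or two fluorophores. `fluorophores_by_class` can
mirror real labeling stoichiometry: a homodimerized motor carries two
tags, while monomeric controls and constructs heterodimerized to an
untagged partner (membrane- or F-actin-tethered) carry one. Each
fluorophore has an exponential photobleaching lifetime (default rate
0.01 s⁻¹) and a two-state blinking chain (off-rate 0.05 s⁻¹, on-rate
0.5 s⁻¹), giving on-times of tens of frames; brightness per fluorophore
is drawn once with CV 0.3 (matching the relative spread of measured
single-fluorophore intensity populations), truncated away from negative
values. Expected dimer intensity is exactly twice the monomer's.

Four motion classes are simulated along the axis coordinate *s*:

- **static** — fixed uniform-random position;
- **diffusive** — 1-D Brownian motion with D = 8 μm²/s (free
  cytoplasmic protein scale), reflected at base and tip. The ≥10
  sub-steps per frame span the exposure window, so the rendered image
  integrates the sub-frame path (motion blur); one coarse step bridges
  the dark remainder of the interval. The per-frame truth position is
  the exposure-window centroid;
- **processive** — constant velocity drawn from a normal truncated at
  zero (mean 100, SD 50 nm/s), tip-ward, position clipped at the tip;
- **stepper** — piecewise-constant motion: exponential dwells (mean
  5 s) interrupted by tip-ward jumps uniform on 100–200 nm. Start
  positions leave room for the expected travel.

Drift is a parametric per-frame displacement (linear trend plus a
sinusoid) applied to emitter positions. Reproducibility: one master
seed; every molecule draws from a `SeedSequence` sub-stream keyed by
its id, so tracks are stable under reordering, and identical configs
produce bit-identical outputs.

What the simulator does **not** emulate — and therefore what passing
tests do not show about real data: tissue autofluorescence and
structured background; axial (z) diffusion, defocus, or the light-sheet
illumination profile; protein exchange with the cell body through the
open base of the protrusion (the tube is closed); bending or growth of
the protrusion; non-uniform labeling. The closed-base point matters for
the diffusing-control phenotype (below).

## Drift registration

Phase-only correlation with a Hann window and a regularized cross-power
spectrum (ε = 10⁻¹⁰·max|C|). Subpixel refinement is a 3-point parabolic
fit per axis by default, or local DFT upsampling (exact on band-limited
shifts) when accuracy matters more than speed. The subsequent
least-squares image matching step runs Gauss–Newton on the intensity
residual with gain and offset terms; Huber reweighting (k = 2.5 robust
SDs) is essential in practice because a fluorophore that blinks or
bleaches between the two frames is one-sided localized content that
otherwise biases the plain least-squares shift by ~0.1 px.

Confidence gating: a frame's estimate is trusted when the correlation
peak ≥ 0.2, the peak is ≥ 2.5× the strongest secondary peak, and the
implied drift rate is ≤ 1 px/frame relative to the last trusted frame
(physical stage drift is slow and smooth; a sparse scene of a few
molecules produces locks of one molecule onto a different one, offset
by their separation). When fewer than half the frames are confident the
movie is declared unregistrable and a zero trace is returned, flagged —
in a scene whose only content is the moving molecules under study,
"drift" is unidentifiable from collective motion, and applying such an
estimate would subtract the very signal being measured. Reference
mode "first" (default) registers everything to frame 0 and does not
accumulate error; "sequential" chains adjacent-frame shifts and random-
walks, so it needs higher SNR for the same accuracy. Correction
resamples frames by the negated trace (cubic spline default; nearest
for count-preserving tests) and marks out-of-field pixels NaN.

## Spot detection and photometry

Difference-of-Gaussians at scales (σ, 2σ) matched to the PSF, threshold
at 5 MAD-based noise SDs, local maxima refined by bounded 2-D Gaussian
fits, duplicates within 2σ merged keeping the brighter. Two quality
gates reject candidates that are not single stationary emitters: fitted
width above 2× the PSF σ (motion-blur streaks, aggregates), and
amplitude below 5× the robust noise of the local annulus (shot-noise
speckle riding on an elevated pedestal, e.g. on a blur streak — the
global threshold cannot see the pedestal). Photometry uses a circular
aperture of radius 3σ (98.9% encircled energy) with the background as
the median of a 4σ–6σ annulus; apertures clipped by the field edge are
flagged and excluded from population fits.

Line-scan profiles are sampled by cubic-spline interpolation (linear
interpolation broadens a ~1 px peak measurably); when comparing camera
profiles against the PSF, the pixel-integration broadening is removed
in quadrature (σ² → σ² − px²/12). A fitted width more than 20% above
the PSF σ flags a non-point source; a doublet at 2σ separation fits
≈ √2σ wide and is reliably flagged.

Quantal populations: 1-D Gaussian mixtures for k = 1…k_max fitted by
EM (scikit-learn, 5 initializations, fixed random state for
determinism), order chosen by BIC with ties toward smaller k. The
default leaves population means free; a quantal-constrained mode
(means = Q·(1…k), shared variance) exists for small samples. On the
1:1 monomer/dimer benchmark at per-fluorophore CV 0.3 the Bayes-optimal
assignment accuracy is itself only ≈ 92%, so measured accuracies
fluctuate around that value and can dip below 90% at some seeds; the
mean-intensity ratio near 2.0 is the robust signature.

## Kymographs, linking, classification

Kymographs sample each frame by bilinear interpolation every bin
(default one pixel, 162.5 nm) along the axis polyline, combining 3
perpendicular samples by max (mean optional; mean ≤ max everywhere).
Storage is (distance, frame); display orientation is a view.

Linking is greedy frame-to-frame nearest neighbor: links cost their
Euclidean displacement, are rejected beyond 650 nm (≈3× the fastest
expected dimer displacement per 1-s frame) regardless of gap length,
and may bridge ≤2 missing frames (blinking). Assignment order is
(distance, detection index), so results are deterministic. Greedy
rather than global assignment is adequate because labeling density is
experimentally tuned to ≪1 molecule/μm; denser scenes are out of
contract. With 100-ms frames a 2 μm/s motor still moves only ~1.2 px
per frame and links fine; the same motor at 1-s frames outruns the
radius and is flagged under-sampled.

Classification of a projected trajectory applies rules in order:

1. *transient* if the observed span is ≤1 frame, or if the median
   fitted spot width exceeds 1.2× the PSF σ — motion blur marks a
   molecule diffusing faster than the exposure can freeze (measured
   widths: stationary classes 149–172 nm, diffusive median 196 nm).
   Minority wide detections within a narrow track are excluded from
   its series instead (they are a diffusing molecule passing through
   the link radius), and isolated end points that jump more than
   max(5 track-noise SDs, 250 nm) — larger than any single motor
   step — are trimmed as linker grabs.
2. *static* if both the endpoint displacement and the OLS-trend
   displacement are below 3·σ_loc·√2 (the noise scale of a difference
   of two noisy endpoints; either measure alone is fooled by endpoint
   noise or by non-monotonic contamination).
3. Otherwise constant, linear and staircase models compete by BIC: a
   winning positive-slope line is *processive*, a winning staircase
   with ≥2 plateaus is *stepwise*, a winning constant is *static*, a
   negative-slope line is *unclassified*. A true continuous ramp loses
   to the linear model on parameter count, so no separate ramp veto is
   needed.

## Velocity and steps

Velocity is the OLS slope over the whole track (a segment-wise option
exists but is off by default), with stderr from residuals; population
summaries use the sample SD (n−1) and 25 nm/s histogram bins.
Retrograde velocities and steps keep their negative sign.

Step detection is greedy binary segmentation of s(t): repeatedly place
the changepoint with the largest RSS reduction while the criterion
n·ln(RSS/n) + penalty·(1 + 3(m−1))·ln n improves. Each plateau beyond
the first costs three parameter units — its mean plus a double-weighted
location term, the modified-BIC convention for changepoint problems
(the location is optimized over n candidates, so an ordinary BIC count
overfits pure noise). The penalty multiplier defaults to 1.0 and is
exposed. Adjacent plateaus closer than the minimum detectable step
(2× the localization SD) are merged afterwards. On the standard
staircase benchmark (150 nm steps, 5-frame dwells, 20 nm noise) this
recovers step sizes within a few nm of truth with no missed steps and
≈0 false steps per noise-only track; detected steps integrate exactly
to the net plateau displacement. Fits with >5 steps of ≤2-frame median
dwell are flagged ramp-like.

## Pipeline, truth matching, benchmarks

`run_pipeline` chains simulate/load → register → detect → link/classify
→ kymograph → motility from one config, stamps outputs with the config
hash, aggregates warnings (clipped apertures, low-confidence drift,
under-sampling), and — with ground truth available — produces a
recovery report. Truth matching is one-to-one greedy: candidate pairs
are eligible when the 75th-percentile per-frame distance is ≤500 nm
(a quantile, so one contaminated link does not disqualify a faithful
track) and are consumed in order of mean distance divided by overlap
length, favoring long faithful tracks over short coincidental ones.
Diffusive molecules are compared against their sub-frame exposure path,
since a blurred detection localizes part of the path rather than its
centroid.

Benchmark problem sizes were chosen to be statistically meaningful yet
quick: the drift benchmark uses one 50-frame 128×128 movie of 30 static
monomeric fiducials at SNR ~10 with <3 px of injected linear+sinusoidal
drift; the quantal benchmark measures 200 rendered molecules; velocity
uses 50 synthetic tracks plus one rendered movie for the ridge check;
steps use 100 staircase replicates with matched noise controls; the
class-confusion benchmark distributes 200 molecules over 67 independent
movies of 3 (0.3 molecules/μm, inside the sparse-labeling regime) with
construct-faithful stoichiometry and no injected drift — registration
is disabled there because those movies contain nothing but the moving
molecules themselves.

## Known limitations

- **Optical crowding.** Molecules placed within ~600 nm of each other
  are not resolvable at a 152-nm PSF; their detections merge and the
  matcher scores a miss plus a confusion. At 0.3 molecules/μm this
  affects a few percent of molecules per benchmark and is the dominant
  term in static/stepper recall fluctuations between seeds.
- **Stepper/processive ambiguity.** Exponential dwells with mean 5 s
  occasionally produce realizations with many near-adjacent steps that
  are genuinely ramp-like; those classify as processive. Stepwise
  recall is therefore typically 0.7–0.9 depending on the seed.
- **The one-frame phenotype of diffusing molecules is captured by the
  classifier, not by track spans.** In the closed-tube model a
  1000-photon fluorophore never leaves focus or the field, so its blur
  features stay detectable every frame; reflected 1-D diffusion has a
  ~1.3 s position-mixing time, and the motor-tuned linker deliberately
  bridges 650-nm/2-frame gaps — so only ~30% of diffusive detections
  end up in single-frame tracks even though matched diffusive molecules
  are classified transient at ~90%. In real tissue, freely diffusing
  molecules exchange with the cell-body pool through the open base
  (mean residence ~L²/3D ≈ 4 s) and vanish; modeling that exchange is
  the main avenue for closing this gap.
- **Drift from sparse scenes is unidentifiable.** A coherently moving
  bright molecule is image-wise indistinguishable from stage drift; the
  estimator refuses (zero trace, flagged) rather than guessing, and
  real use should register on fiducial-rich content.
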