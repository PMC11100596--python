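"""Single-molecule spot detection, photometry and quantal classification.

A punctum emitted by one fluorophore is a diffraction-limited Gaussian
of width set by the PSF.  Detection runs a difference-of-Gaussians
filter matched to the PSF scale, thresholds local maxima at ``k`` robust
(MAD-based) noise SDs, and refines each candidate with a 2-D Gaussian
fit.  Photometry sums pixel values in a circular aperture and subtracts
the median of a surrounding annulus ("adding all pixel values
encompassing the punctum, then subtracting the background").  Averaged
line-scan profiles validate that puncta match the PSF, and a 1-D
Gaussian mixture over summed intensities separates the quantal
populations: one-fluorophore puncta (quantal intensity Q) versus
two-fluorophore puncta at ~2Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.mixture import GaussianMixture

MAD_TO_SD = 1.4826


@dataclass
class PSFModel:
    """Isotropic Gaussian PSF approximation."""

    sigma_nm: float
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("sigma and pixel size must be positive")

    @property
    def sigma_px(self) -> float:
        return self.sigma_nm / self.pixel_size_nm

    @classmethod
    def from_optics(
        cls,
        emission_wavelength_nm: float = 580.0,
        numerical_aperture: float = 0.8,
        pixel_size_nm: float = 162.5,
    ) -> "PSFModel":
        """Gaussian PSF sigma ~ 0.21 * lambda / NA (widefield approximation)."""
        return cls(
            sigma_nm=0.21 * emission_wavelength_nm / numerical_aperture,
            pixel_size_nm=pixel_size_nm,
        )


@dataclass
class Detection:
    """One localized punctum in one frame."""

    frame: int
    x_px: float
    y_px: float
    sum_intensity: float
    local_background: float
    fit_sigma_nm: float
    snr: float
    amplitude: float = np.nan
    s_nm: float = np.nan  # along-axis coordinate, set by projection
    flags: set = field(default_factory=set)
    index: int = -1  # stable ordering for deterministic linking


@dataclass
class PopulationFit:
    """Gaussian-mixture decomposition of punctum summed intensities."""

    k: int
    means: np.ndarray  # strictly increasing
    sds: np.ndarray
    weights: np.ndarray
    counts: np.ndarray
    assignments: np.ndarray  # population index per detection, sorted order
    quantal_intensity: float  # mean of the lowest population
    mean_ratio: float | None  # mean_2 / mean_1 when k >= 2
    bic: np.ndarray  # BIC for each candidate k (1..k_max)


def robust_noise_sd(image: np.ndarray) -> float:
    """MAD-based SD estimate, insensitive to sparse bright spots."""
    vals = image[np.isfinite(image)]
    med = np.median(vals)
    return MAD_TO_SD * float(np.median(np.abs(vals - med)))


def _gauss2d(coords, amplitude, x0, y0, sigma, offset):
    x, y = coords
    return (
        amplitude * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2))
        + offset
    ).ravel()


def _fit_gaussian_2d(
    image: np.ndarray, x_init: float, y_init: float, sigma_init: float, radius: int
) -> tuple[float, float, float, float, float] | None:
    h, w = image.shape
    y0 = int(round(y_init))
    x0 = int(round(x_init))
    sl = (
        slice(max(0, y0 - radius), min(h, y0 + radius + 1)),
        slice(max(0, x0 - radius), min(w, x0 + radius + 1)),
    )
    patch = image[sl]
    if patch.size < 9 or not np.all(np.isfinite(patch)):
        return None
    yy, xx = np.mgrid[sl[0], sl[1]]
    offset0 = float(np.median(patch))
    amp0 = float(patch.max() - offset0)
    if amp0 <= 0:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _gauss2d,
                (xx, yy),
                patch.ravel(),
                p0=(amp0, x_init, y_init, sigma_init, offset0),
                bounds=(
                    (0, x_init - radius, y_init - radius, 0.3 * sigma_init, -np.inf),
                    (np.inf, x_init + radius, y_init + radius, 4 * sigma_init, np.inf),
                ),
                maxfev=200,
            )
    except (RuntimeError, ValueError):
        return None
    amplitude, x, y, sigma, offset = popt
    return float(amplitude), float(x), float(y), float(sigma), float(offset)


def detect_spots(
    frame_image: np.ndarray,
    psf: PSFModel,
    threshold_k: float = 5.0,
    frame_index: int = 0,
    aperture_radius_px: float | None = None,
    max_sigma_factor: float = 2.0,
) -> list[Detection]:
    """Detect diffraction-limited puncta in one (drift-corrected) frame.

    Returns an empty list on blank frames; detections whose photometry
    aperture is clipped by the frame edge or by out-of-field sentinels
    carry the ``'clipped'`` flag.  Two quality gates reject candidates
    that are not single stationary emitters: a fitted width more than
    ``max_sigma_factor`` times the PSF sigma (a diffraction-limited
    punctum fits at the PSF width; motion-blurred streaks, occupation
    maxima of a diffusing molecule's exposure path, and aggregates fit
    wider), and an amplitude below ``threshold_k`` times the robust
    noise of the local annulus (shot-noise speckle riding on an
    elevated pedestal such as a blur streak).
    """
    image = np.asarray(frame_image, dtype=np.float64)
    nan_mask = ~np.isfinite(image)
    work = image.copy()
    if nan_mask.any():
        work[nan_mask] = np.nanmedian(image)
    sigma_px = psf.sigma_px
    bandpass = ndimage.gaussian_filter(work, sigma_px) - ndimage.gaussian_filter(
        work, 2.0 * sigma_px
    )
    noise = robust_noise_sd(bandpass[~nan_mask]) if (~nan_mask).any() else 0.0
    if noise == 0:
        noise = bandpass.std() or 1.0
    threshold = threshold_k * noise
    local_max = ndimage.maximum_filter(bandpass, size=3) == bandpass
    cand = np.argwhere(local_max & (bandpass > threshold))
    if cand.size == 0:
        return []
    # brightest first so duplicate merging keeps the stronger punctum
    order = np.argsort(-bandpass[cand[:, 0], cand[:, 1]], kind="stable")
    cand = cand[order]

    image_noise = robust_noise_sd(image[~nan_mask]) if (~nan_mask).any() else 1.0
    fit_radius = max(3, int(np.ceil(3 * sigma_px)))
    if aperture_radius_px is None:
        aperture_radius_px = float(np.ceil(3 * sigma_px))
    detections: list[Detection] = []
    for iy, ix in cand:
        fit = _fit_gaussian_2d(work, float(ix), float(iy), sigma_px, fit_radius)
        if fit is None:
            x, y, sigma, amp = float(ix), float(iy), sigma_px, float(
                work[iy, ix] - np.median(work)
            )
            flags = {"fit_failed"}
        else:
            amp, x, y, sigma, _ = fit
            flags = set()
            if sigma > max_sigma_factor * sigma_px:
                continue  # blurred streak or aggregate, not a punctum
        if any(np.hypot(d.x_px - x, d.y_px - y) < 2 * sigma_px for d in detections):
            continue  # duplicate of a brighter punctum
        sum_int, background, clipped = measure_sum_intensity(
            image,
            (x, y),
            aperture_radius=aperture_radius_px,
            annulus_radii=(4 * sigma_px, 6 * sigma_px),
        )
        local_noise = _annulus_noise(
            work, (x, y), (4 * sigma_px, 6 * sigma_px)
        )
        noise_floor = max(local_noise, 1e-12)
        if amp < threshold_k * local_noise:
            continue  # speckle on a pedestal, not a punctum
        if clipped:
            flags.add("clipped")
        detections.append(
            Detection(
                frame=frame_index,
                x_px=x,
                y_px=y,
                sum_intensity=sum_int,
                local_background=background,
                fit_sigma_nm=sigma * psf.pixel_size_nm,
                snr=amp / noise_floor,
                amplitude=amp,
                flags=flags,
            )
        )
    detections.sort(key=lambda d: (d.y_px, d.x_px))
    for i, det in enumerate(detections):
        det.index = i
    return detections


def _annulus_noise(
    image: np.ndarray, center: tuple[float, float], radii: tuple[float, float]
) -> float:
    """Robust noise SD of the annulus around a candidate punctum."""
    h, w = image.shape
    cx, cy = center
    r_out = radii[1]
    y0 = max(0, int(np.floor(cy - r_out)))
    y1 = min(h, int(np.ceil(cy + r_out)) + 1)
    x0 = max(0, int(np.floor(cx - r_out)))
    x1 = min(w, int(np.ceil(cx + r_out)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    vals = image[y0:y1, x0:x1][(dist >= radii[0]) & (dist <= radii[1])]
    vals = vals[np.isfinite(vals)]
    if vals.size < 8:
        return 0.0
    med = np.median(vals)
    return MAD_TO_SD * float(np.median(np.abs(vals - med)))


def measure_sum_intensity(
    image: np.ndarray,
    center: tuple[float, float],
    aperture_radius: float,
    annulus_radii: tuple[float, float],
) -> tuple[float, float, bool]:
    """Background-subtracted summed intensity of one punctum.

    ``sum = sum(aperture) - median(annulus) * n_aperture_pixels``; the
    returned background is the annulus median per pixel.  The third
    element flags apertures clipped by the frame edge or touching
    out-of-field (NaN) pixels; clipped measurements should be excluded
    from population fitting.
    """
    if annulus_radii[0] < aperture_radius:
        raise ValueError("annulus inner radius must be >= aperture radius")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    cx, cy = center
    r_out = annulus_radii[1]
    clipped = (
        cx - aperture_radius < -0.5
        or cx + aperture_radius > w - 0.5
        or cy - aperture_radius < -0.5
        or cy + aperture_radius > h - 0.5
    )
    y0 = max(0, int(np.floor(cy - r_out)))
    y1 = min(h, int(np.ceil(cy + r_out)) + 1)
    x0 = max(0, int(np.floor(cx - r_out)))
    x1 = min(w, int(np.ceil(cx + r_out)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    sub = image[y0:y1, x0:x1]
    in_ap = dist <= aperture_radius
    in_ann = (dist >= annulus_radii[0]) & (dist <= annulus_radii[1])
    ap_vals = sub[in_ap]
    ann_vals = sub[in_ann]
    ann_vals = ann_vals[np.isfinite(ann_vals)]
    if not np.all(np.isfinite(ap_vals)):
        clipped = True
        ap_vals = ap_vals[np.isfinite(ap_vals)]
    background = float(np.median(ann_vals)) if ann_vals.size else 0.0
    total = float(ap_vals.sum() - background * ap_vals.size)
    return total, background, clipped


def line_scan_profile(
    image: np.ndarray,
    center: tuple[float, float],
    direction: tuple[float, float] = (1.0, 0.0),
    half_length_px: float = 5.0,
    width_px: int = 1,
    spacing_px: float = 0.25,
    pixel_size_nm: float = 1.0,
    order: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity profile through a punctum along ``direction``.

    Samples by spline interpolation (order 3 by default, which does not
    broaden a ~1-px-wide peak the way linear interpolation does) every
    ``spacing_px`` along a line of +/- ``half_length_px``, averaging
    ``width_px`` parallel lines.  Returns (offsets in nm, intensities).
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.hypot(*direction)
    normal = np.array([-direction[1], direction[0]])
    ts = np.arange(-half_length_px, half_length_px + spacing_px / 2, spacing_px)
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    cx, cy = center
    profiles = []
    for off in offsets:
        xs = cx + ts * direction[0] + off * normal[0]
        ys = cy + ts * direction[1] + off * normal[1]
        profiles.append(
            ndimage.map_coordinates(
                np.asarray(image, dtype=float), [ys, xs], order=order,
                mode="nearest",
            )
        )
    return ts * pixel_size_nm, np.mean(profiles, axis=0)


def _gauss1d(x, amplitude, center, sigma, offset):
    return amplitude * np.exp(-((x - center) ** 2) / (2 * sigma**2)) + offset


@dataclass
class PSFComparison:
    fitted_sigma_nm: float
    rms_discrepancy: float
    width_excess: float  # (fitted - psf) / psf
    flagged: bool
    mean_profile: tuple[np.ndarray, np.ndarray] | None = None


def compare_profile_to_psf(
    profiles: list[tuple[np.ndarray, np.ndarray]],
    psf: PSFModel,
    width_excess_tol: float = 0.2,
    correct_pixelation: bool = False,
) -> PSFComparison:
    """Compare averaged punctum line scans against the Gaussian PSF.

    Profiles are baseline-subtracted, peak-aligned, peak-normalized and
    averaged on a common grid; a Gaussian is fitted to the average and
    the normalized RMS discrepancy is evaluated over the central
    +/- 3 sigma.  A fitted width exceeding the PSF sigma by more than
    ``width_excess_tol`` flags a non-point source (e.g. a doublet).

    ``correct_pixelation=True`` removes the camera pixel-integration
    broadening from the fitted width in quadrature
    (``sigma^2 -> sigma^2 - px^2/12``); use it when the profiles come
    from camera images rather than analytic curves.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if len(profiles) < 3:
        warnings.warn("fewer than 3 profiles; average is noisy", stacklevel=2)
    sigma = psf.sigma_nm
    grid = np.linspace(-4 * sigma, 4 * sigma, 129)
    aligned = []
    for s, v in profiles:
        s = np.asarray(s, dtype=float)
        v = np.asarray(v, dtype=float)
        baseline = min(v[0], v[-1])
        v = v - baseline
        ipk = int(np.argmax(v))
        # parabolic peak interpolation for subsample alignment
        if 0 < ipk < len(v) - 1:
            denom = v[ipk - 1] - 2 * v[ipk] + v[ipk + 1]
            frac = 0.5 * (v[ipk - 1] - v[ipk + 1]) / denom if denom != 0 else 0.0
        else:
            frac = 0.0
        ds = s[1] - s[0]
        s_peak = s[ipk] + frac * ds
        peak_val = v[ipk]
        if peak_val <= 0:
            continue
        aligned.append(np.interp(grid, s - s_peak, v / peak_val, left=0, right=0))
    if not aligned:
        raise ValueError("no profile with a positive peak")
    mean_profile = np.mean(aligned, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = optimize.curve_fit(
            _gauss1d,
            grid,
            mean_profile,
            p0=(1.0, 0.0, sigma, 0.0),
            maxfev=500,
        )
    amp, center, fitted_sigma, offset = popt
    fitted_sigma = abs(float(fitted_sigma))
    if correct_pixelation:
        pix_var = psf.pixel_size_nm**2 / 12.0
        fitted_sigma = float(np.sqrt(max(fitted_sigma**2 - pix_var, 1e-12)))
    core = np.abs(grid - center) <= 3 * sigma
    model = _gauss1d(grid, 1.0, center, sigma, 0.0)
    observed = (mean_profile - offset) / amp if amp != 0 else mean_profile
    rms = float(np.sqrt(np.mean((observed[core] - model[core]) ** 2)))
    excess = fitted_sigma / sigma - 1.0
    return PSFComparison(
        fitted_sigma_nm=fitted_sigma,
        rms_discrepancy=rms,
        width_excess=float(excess),
        flagged=excess > width_excess_tol,
        mean_profile=(grid, mean_profile),
    )


def classify_quantal_populations(
    intensities: np.ndarray,
    k_max: int = 3,
    mode: str = "free",
    random_state: int = 0,
) -> PopulationFit:
    """Decompose summed intensities into quantal populations.

    Gaussian mixtures with k = 1..k_max are fitted by EM; k is chosen by
    the Bayesian information criterion with ties broken toward smaller
    k.  The quantal intensity Q is the mean of the lowest population;
    ``mean_ratio`` is mean2/mean1 (expected ~2 for a monomer/dimer mix).
    ``mode='quantal'`` constrains the means to Q*(1..k).
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need at least 10 finite intensities, got {x.size}")
    if mode not in ("free", "quantal"):
        raise ValueError("mode must be 'free' or 'quantal'")
    if np.ptp(x) == 0:
        n = x.size
        return PopulationFit(
            k=1,
            means=np.array([x[0]]),
            sds=np.array([0.0]),
            weights=np.array([1.0]),
            counts=np.array([n]),
            assignments=np.zeros(n, dtype=int),
            quantal_intensity=float(x[0]),
            mean_ratio=None,
            bic=np.full(k_max, np.nan),
        )
    X = x[:, None]
    bics = np.full(k_max, np.inf)
    models: list = []
    for k in range(1, k_max + 1):
        if mode == "free":
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=5,
                init_params="k-means++",
                random_state=random_state,
                reg_covar=1e-6 * float(np.var(x)),
            )
            try:
                gm.fit(X)
            except ValueError:
                models.append(None)
                continue
            bics[k - 1] = gm.bic(X)
            models.append(gm)
        else:
            fit = _fit_quantal_constrained(x, k)
            bics[k - 1] = fit["bic"]
            models.append(fit)
    best_k = int(np.argmin(np.round(bics, 9))) + 1  # argmin takes smaller k on ties
    model = models[best_k - 1]
    if model is None:
        raise RuntimeError("EM failed for the selected k")
    if mode == "free":
        means = model.means_.ravel()
        sds = np.sqrt(model.covariances_.ravel())
        weights = model.weights_
        raw = model.predict(X)
    else:
        means = model["means"]
        sds = model["sds"]
        weights = model["weights"]
        raw = model["assignments"]
    order = np.argsort(means)
    remap = np.empty_like(order)
    remap[order] = np.arange(best_k)
    assignments = remap[raw]
    means, sds, weights = means[order], sds[order], weights[order]
    counts = np.bincount(assignments, minlength=best_k)
    return PopulationFit(
        k=best_k,
        means=means,
        sds=sds,
        weights=weights,
        counts=counts,
        assignments=assignments,
        quantal_intensity=float(means[0]),
        mean_ratio=float(means[1] / means[0]) if best_k >= 2 else None,
        bic=bics,
    )


def _fit_quantal_constrained(x: np.ndarray, k: int, n_iter: int = 200) -> dict:
    """EM with means constrained to Q*(1..k) and a shared variance."""
    n = x.size
    q = float(np.percentile(x, 25)) or float(x.mean())
    var = float(np.var(x)) / max(k, 1)
    w = np.full(k, 1.0 / k)
    mult = np.arange(1, k + 1)
    ll_old = -np.inf
    resp = np.full((n, k), 1.0 / k)
    for _ in range(n_iter):
        mu = q * mult
        log_pdf = (
            -0.5 * np.log(2 * np.pi * var)
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var
            + np.log(np.maximum(w[None, :], 1e-300))
        )
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        resp = np.exp(log_pdf - lse[:, None])
        w = resp.mean(axis=0)
        denom = float((resp * mult[None, :] ** 2).sum())
        q = float((resp * mult[None, :] * x[:, None]).sum() / denom)
        var = float((resp * (x[:, None] - q * mult[None, :]) ** 2).sum() / n)
        var = max(var, 1e-12)
        ll = float(lse.sum())
        if abs(ll - ll_old) < 1e-10 * (1 + abs(ll)):
            break
        ll_old = ll
    n_params = 1 + 1 + (k - 1)  # Q, shared variance, free weights
    bic = -2 * ll_old + n_params * np.log(n)
    assignments = np.argmax(resp, axis=1)
    return {
        "means": q * mult.astype(float),
        "sds": np.full(k, np.sqrt(var)),
        "weights": w,
        "assignments": assignments,
        "bic": bic,
        "q": q,
    }


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Tabulate detections for CSV output."""
    return pd.DataFrame(
        {
            "frame": [d.frame for d in detections],
            "x_px": [d.x_px for d in detections],
            "y_px": [d.y_px for d in detections],
            "sum_intensity": [d.sum_intensity for d in detections],
            "background": [d.local_background for d in detections],
            "fit_sigma_nm": [d.fit_sigma_nm for d in detections],
            "snr": [d.snr for d in detections],
            "s_nm": [d.s_nm for d in detections],
            "flags": [";".join(sorted(d.flags)) for d in detections],
        }
    )


def frame_to_detections(df: pd.DataFrame) -> list[Detection]:
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        flags = set(str(getattr(row, "flags", "")).split(";")) - {"", "nan"}
        out.append(
            Detection(
                frame=int(row.frame),
                x_px=float(row.x_px),
                y_px=float(row.y_px),
                sum_intensity=float(row.sum_intensity),
                local_background=float(row.background),
                fit_sigma_nm=float(row.fit_sigma_nm),
                snr=float(row.snr),
                s_nm=float(getattr(row, "s_nm", np.nan)),
                flags=flags,
                index=i,
            )
        )
    return out
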