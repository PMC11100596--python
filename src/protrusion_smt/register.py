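"""Lateral drift estimation and correction for time-lapse movies.

Drift between frames is estimated by phase-only correlation (POC): the
cross-power spectrum of the two images is normalized to unit modulus,
and its inverse transform peaks at the inter-frame shift.  The integer
peak is refined to subpixel precision either by a three-point parabolic
fit per axis (default) or by locally upsampled correlation, and then
polished by least-squares image matching (LSM) — Gauss-Newton
minimization of the intensity residual with optional gain/offset terms.

Sign convention: ``phase_correlation_shift(a, b)`` returns the
displacement ``(dx, dy)`` *of b relative to a*, i.e. the shift that maps
``a`` onto ``b`` (``b = roll(a, (dy, dx))`` for circular shifts).
Correction therefore resamples each frame by ``-(dx, dy)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.fft import fft2, ifft2
from scipy import ndimage

from protrusion_smt.io import Movie


class DegenerateImageError(ValueError):
    """Image has no usable spectrum (constant, or all-zero after windowing)."""


@dataclass
class DriftTrace:
    """Per-frame displacement of the sample relative to a reference frame."""

    dx_px: np.ndarray
    dy_px: np.ndarray
    peak: np.ndarray  # POC confidence in [0, 1]
    reference_frame: int = 0
    reference_mode: str = "first"
    low_confidence: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dx_px = np.asarray(self.dx_px, dtype=float)
        self.dy_px = np.asarray(self.dy_px, dtype=float)
        self.peak = np.asarray(self.peak, dtype=float)
        if self.low_confidence is None:
            self.low_confidence = np.zeros(self.dx_px.shape, dtype=bool)
        if not (
            self.dx_px.shape == self.dy_px.shape == self.peak.shape
        ):
            raise ValueError("trace arrays must have identical length")
        if not np.all(np.isfinite(self.dx_px)) or not np.all(np.isfinite(self.dy_px)):
            raise ValueError("drift trace entries must be finite")

    def __len__(self) -> int:
        return self.dx_px.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "dx_px": self.dx_px,
                "dy_px": self.dy_px,
                "peak": self.peak,
                "low_confidence": self.low_confidence.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, reference_mode: str = "first") -> "DriftTrace":
        df = pd.read_csv(path)
        return cls(
            dx_px=df["dx_px"].to_numpy(),
            dy_px=df["dy_px"].to_numpy(),
            peak=df["peak"].to_numpy(),
            low_confidence=df.get("low_confidence", 0).to_numpy().astype(bool),
            reference_mode=reference_mode,
        )


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _wrap(idx: int, n: int) -> float:
    return idx - n if idx > n // 2 else idx


def _parabolic_offset(rm: float, r0: float, rp: float) -> float:
    denom = rm - 2.0 * r0 + rp
    if denom == 0:
        return 0.0
    off = 0.5 * (rm - rp) / denom
    return float(np.clip(off, -0.5, 0.5))


def _upsampled_peak(
    cross_power: np.ndarray, coarse: tuple[float, float], factor: int = 20
) -> tuple[float, float]:
    """Refine the correlation peak by local DFT upsampling.

    Evaluates the inverse transform of the unit-modulus cross-power
    spectrum on a fine grid of +/-1 px around the coarse peak.
    """
    h, w = cross_power.shape
    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[None, :]
    offsets = np.arange(-factor, factor + 1) / factor  # +/- 1 px
    best, by, bx = -np.inf, coarse[1], coarse[0]
    for oy in offsets:
        y = coarse[1] + oy
        base = cross_power * np.exp(2j * np.pi * ky * y)
        for ox in offsets:
            x = coarse[0] + ox
            val = np.real(np.sum(base * np.exp(2j * np.pi * kx * x))) / (h * w)
            if val > best:
                best, by, bx = val, y, x
    return bx, by


def phase_correlation_shift(
    image_a: np.ndarray,
    image_b: np.ndarray,
    window: bool = True,
    subpixel_mode: str = "parabolic",
    eps_rel: float = 1e-10,
    _full: bool = False,
):
    """Phase-only correlation shift of ``image_b`` relative to ``image_a``.

    Returns ``(dx, dy, peak)`` where ``peak`` in [0, 1] is the height of
    the normalized correlation peak (1 for a pure shift).  A Hann window
    suppresses edge ringing; the cross-power spectrum is regularized as
    ``C / (|C| + eps)`` with ``eps = eps_rel * max|C|``.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or min(a.shape) < 16:
        raise ValueError("images must be 2-D with at least 16 px per side")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateImageError("constant image has no phase spectrum")
    a = a - a.mean()
    b = b - b.mean()
    if window:
        win = _hann2d(a.shape)
        a = a * win
        b = b * win
    fa = fft2(a)
    fb = fft2(b)
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    eps = eps_rel * mag.max()
    if mag.max() == 0:
        raise DegenerateImageError("zero cross-power spectrum")
    r = np.real(ifft2(cross / (mag + eps)))
    h, w = r.shape
    iy, ix = np.unravel_index(int(np.argmax(r)), r.shape)
    peak = float(np.clip(r[iy, ix], 0.0, 1.0))
    prominence = 1.0
    if _full:
        yy, xx = np.mgrid[0:h, 0:w]
        dy = np.minimum(np.abs(yy - iy), h - np.abs(yy - iy))
        dx_g = np.minimum(np.abs(xx - ix), w - np.abs(xx - ix))
        secondary = float(r[(dy > 4) | (dx_g > 4)].max())
        prominence = r[iy, ix] / max(secondary, 1e-12)
    # peak of ifft sits at index -shift (mod N)
    if subpixel_mode == "parabolic":
        offx = _parabolic_offset(
            r[iy, (ix - 1) % w], r[iy, ix], r[iy, (ix + 1) % w]
        )
        offy = _parabolic_offset(
            r[(iy - 1) % h, ix], r[iy, ix], r[(iy + 1) % h, ix]
        )
        px = _wrap(ix, w) + offx
        py = _wrap(iy, h) + offy
    elif subpixel_mode == "upsample":
        px, py = _upsampled_peak(
            cross / (mag + eps), (_wrap(ix, w), _wrap(iy, h))
        )
    elif subpixel_mode == "none":
        px, py = float(_wrap(ix, w)), float(_wrap(iy, h))
    else:
        raise ValueError(f"unknown subpixel_mode {subpixel_mode!r}")
    if _full:
        return -px, -py, peak, prominence
    return -px, -py, peak


def refine_shift_lsm(
    image_a: np.ndarray,
    image_b: np.ndarray,
    init_shift: tuple[float, float],
    max_iter: int = 25,
    tol: float = 1e-3,
    fit_photometry: bool = True,
    robust_k: float | None = 2.5,
) -> tuple[float, float, bool]:
    """Least-squares image matching refinement of a shift estimate.

    Gauss-Newton minimization of ``sum[a(p) - g * b(p + shift) - o]^2``
    over the shift (and optionally gain ``g`` / offset ``o``), starting
    from ``init_shift``; intended for initial errors below 1 px.
    Returns ``(dx, dy, converged)``; on a singular normal matrix the
    initial shift is returned unconverged.

    With ``robust_k`` set (Huber constant in robust-MAD units, default
    2.5) the normal equations are iteratively reweighted so that
    localized content present in only one image — a fluorophore that
    blinked or bleached between the frames — is downweighted instead of
    dragging the shift; ``robust_k=None`` gives plain least squares.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    dx, dy = float(init_shift[0]), float(init_shift[1])
    g, o = 1.0, 0.0
    margin = int(np.ceil(max(abs(dx), abs(dy)))) + 3
    h, w = a.shape
    if h - 2 * margin < 4 or w - 2 * margin < 4:
        return dx, dy, False
    sl = (slice(margin, h - margin), slice(margin, w - margin))
    converged = False
    for _ in range(max_iter):
        b_shift = ndimage.shift(b, (-dy, -dx), order=3, mode="nearest")
        gy, gx = np.gradient(b_shift)
        bs, gxs, gys = b_shift[sl], gx[sl], gy[sl]
        model = g * bs + o
        resid = (a[sl] - model).ravel()
        cols = [g * gxs.ravel(), g * gys.ravel()]
        if fit_photometry:
            cols += [bs.ravel(), np.ones(bs.size)]
        jac = np.stack(cols, axis=1)
        if robust_k is not None:
            mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if mad > 0:
                z = np.abs(resid) / (robust_k * mad)
                weights = np.ones_like(z)
                big = z > 1.0
                weights[big] = 1.0 / z[big]
                jac_w = jac * weights[:, None]
            else:
                jac_w = jac
        else:
            jac_w = jac
        jtj = jac_w.T @ jac
        try:
            delta = np.linalg.solve(jtj, jac_w.T @ resid)
        except np.linalg.LinAlgError:
            return float(init_shift[0]), float(init_shift[1]), False
        if not np.all(np.isfinite(delta)):
            return float(init_shift[0]), float(init_shift[1]), False
        dx += delta[0]
        dy += delta[1]
        if fit_photometry:
            g += delta[2]
            o += delta[3]
        if np.hypot(delta[0], delta[1]) < tol:
            converged = True
            break
    return dx, dy, converged


def estimate_drift(
    movie: Movie,
    reference_mode: str = "first",
    roi: tuple[slice, slice] | None = None,
    subpixel_mode: str = "parabolic",
    use_lsm: bool = True,
    min_peak: float = 0.2,
    min_prominence: float = 2.5,
    max_step_px: float = 1.0,
    min_confident_fraction: float = 0.5,
) -> DriftTrace:
    """Estimate the per-frame drift trace of a movie.

    ``reference_mode='first'`` registers every frame against frame 0
    (no error accumulation); ``'sequential'`` chains adjacent-frame
    shifts by cumulative sum (robust when the scene decorrelates from
    frame 0).  A frame is *confident* when the POC peak is at least
    ``min_peak``, the peak is at least ``min_prominence`` times the
    strongest secondary peak, and the shift moves no faster than
    ``max_step_px`` per frame from the last confident shift — physical
    stage drift is slow and smooth, whereas a sparse scene of a few
    blinking molecules produces locks of one molecule onto a different
    one, displaced by the multi-pixel distance between the two.
    Non-confident frames keep
    their estimate but are flagged; when fewer than
    ``min_confident_fraction`` of frames are confident, the whole movie
    is judged unregistrable and a zero trace is returned with every
    frame flagged.
    """
    if movie.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    if reference_mode not in ("first", "sequential"):
        raise ValueError("reference_mode must be 'first' or 'sequential'")
    frames = movie.data
    if roi is not None:
        frames = frames[(slice(None),) + tuple(roi)]
    frames = np.nan_to_num(frames, nan=0.0)
    n = frames.shape[0]
    dx = np.zeros(n)
    dy = np.zeros(n)
    peak = np.ones(n)
    flags = np.zeros(n, dtype=bool)
    n_degenerate = 0
    last_ok = (0.0, 0.0)
    last_ok_frame = 0
    for t in range(1, n):
        ref = frames[0] if reference_mode == "first" else frames[t - 1]
        try:
            px, py, pk, prom = phase_correlation_shift(
                ref, frames[t], subpixel_mode=subpixel_mode, _full=True
            )
        except DegenerateImageError:
            n_degenerate += 1
            px, py, pk, prom = 0.0, 0.0, 0.0, 0.0
        if reference_mode == "first":
            # allowance grows with the outage length but is capped so a
            # large constant false offset can never become plausible
            elapsed = min(t - last_ok_frame, 5)
            rate = np.hypot(px - last_ok[0], py - last_ok[1]) / elapsed
        else:
            rate = np.hypot(px, py)
        confident = (
            pk >= min_peak and prom >= min_prominence and rate <= max_step_px
        )
        if confident:
            last_ok = (px, py)
            last_ok_frame = t
        if pk < 0.05:
            # degenerate correlation: inherit the previous shift
            prev_dx = dx[t - 1] if reference_mode == "first" else 0.0
            prev_dy = dy[t - 1] if reference_mode == "first" else 0.0
            step_x, step_y = prev_dx, prev_dy
            confident = False
        else:
            if use_lsm:
                px, py, _ = refine_shift_lsm(ref, frames[t], (px, py))
            step_x, step_y = px, py
        flags[t] = not confident
        if reference_mode == "first":
            dx[t], dy[t] = step_x, step_y
        else:
            dx[t] = dx[t - 1] + step_x
            dy[t] = dy[t - 1] + step_y
        peak[t] = pk
    if n_degenerate == n - 1:
        raise DegenerateImageError("all frames degenerate; cannot estimate drift")
    if (n - 1 - int(flags[1:].sum())) < min_confident_fraction * (n - 1):
        dx = np.zeros(n)
        dy = np.zeros(n)
        flags = np.ones(n, dtype=bool)
        flags[0] = False
    return DriftTrace(
        dx_px=dx,
        dy_px=dy,
        peak=peak,
        reference_frame=0,
        reference_mode=reference_mode,
        low_confidence=flags,
    )


def apply_drift_correction(
    movie: Movie, trace: DriftTrace, interpolation: str = "cubic"
) -> Movie:
    """Resample every frame by the negated drift trace.

    Pixels that map outside the original field become NaN sentinels;
    valid pixels stay non-negative.  ``interpolation`` is ``'cubic'``
    (spline, default) or ``'nearest'`` (count-preserving for integer
    shifts).
    """
    if len(trace) != movie.n_frames:
        raise ValueError(
            f"trace length {len(trace)} != movie length {movie.n_frames}"
        )
    order = {"cubic": 3, "nearest": 0, "linear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    h, w = movie.shape
    out = np.empty_like(movie.data, dtype=np.float64)
    ys = np.arange(h)[:, None]
    xs = np.arange(w)[None, :]
    for t in range(movie.n_frames):
        dx, dy = trace.dx_px[t], trace.dy_px[t]
        if dx == 0 and dy == 0:
            out[t] = movie.data[t]
            continue
        frame = np.nan_to_num(movie.data[t], nan=0.0)
        shifted = ndimage.shift(frame, (-dy, -dx), order=order, mode="nearest")
        shifted = np.clip(shifted, 0.0, None)
        # out(y, x) samples in(y + dy, x + dx): mark out-of-field pixels
        src_y = ys + dy
        src_x = xs + dx
        invalid = (src_y < -0.5) | (src_y > h - 0.5) | (src_x < -0.5) | (src_x > w - 0.5)
        shifted[np.broadcast_to(invalid, shifted.shape)] = np.nan
        out[t] = shifted
    corrected = movie.copy_with(out)
    corrected.meta = dict(movie.meta, drift_corrected=True)
    return corrected
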