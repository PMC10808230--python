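"""2D structure factor of particle positions and Gaussian-peak interval fit.

S(q) = <|sum_j exp(-i q . r_j)|^2 / N> on the reciprocal lattice of the
periodic box, integrated over the angle of q (a sum over lattice vectors per
|q| bin) and averaged over frames.  The pattern interval is 2*pi/mu from a
least-squares Gaussian fit A / (sqrt(2 pi) sigma) * exp(-(q - mu)^2 / 2
sigma^2) around the first interior peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class StructureFactor:
    q_bins: np.ndarray        # bin centers, 1/µm
    s_values: np.ndarray
    dq: float
    peak: tuple[float, float, float] | None = None   # (A, mu, sigma)

    @property
    def interval(self) -> float | None:
        return 2 * np.pi / self.peak[1] if self.peak else None


def _frame_s2d(points: np.ndarray, box: float, n_max: int) -> np.ndarray:
    """|sum exp(-i q.r)|^2 / N on the (2*n_max+1)^2 reciprocal lattice."""
    n = np.arange(-n_max, n_max + 1)
    phase_x = np.exp(-2j * np.pi * np.outer(n, points[:, 0]) / box)
    phase_y = np.exp(-2j * np.pi * np.outer(n, points[:, 1]) / box)
    amp = np.einsum("xj,yj->yx", phase_x, phase_y)
    return (amp * amp.conj()).real / len(points)


def structure_factor(frames, box: float, dq: float | None = None,
                     n_max: int = 30) -> StructureFactor:
    """Angularly integrated, time-averaged S(q).

    ``frames`` is one (N, 2) position array or a sequence of them (the time
    average); ``dq`` defaults to the reciprocal lattice spacing 2*pi/box.
    """
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
    frames = [np.asarray(f, float) for f in frames]
    if not frames or any(len(f) == 0 for f in frames):
        raise ValueError("structure factor of an empty point set is undefined")
    if dq is None:
        dq = 2 * np.pi / box
    n = np.arange(-n_max, n_max + 1)
    qx, qy = np.meshgrid(2 * np.pi * n / box, 2 * np.pi * n / box)
    qmag = np.hypot(qx, qy)
    s2d = np.zeros_like(qmag)
    for pts in frames:
        s2d += _frame_s2d(pts, box, n_max)
    s2d /= len(frames)
    q_max = 2 * np.pi * n_max / box          # keep the fully sampled annuli
    nbins = int(np.floor(q_max / dq)) + 1
    # bins centered on multiples of dq so pure Bragg peaks sit on centers
    which = np.round(qmag / dq).astype(int)
    valid = (qmag <= q_max) & (which < nbins)
    sums = np.bincount(which[valid], weights=s2d[valid], minlength=nbins)
    counts = np.bincount(which[valid], minlength=nbins)
    s_binned = sums / np.maximum(counts, 1)
    centers = np.arange(nbins) * dq
    return StructureFactor(centers, s_binned, dq)


def _gauss(q, A, mu, sigma):
    return A / (np.sqrt(2 * np.pi) * sigma) * np.exp(-(q - mu) ** 2
                                                     / (2 * sigma ** 2))


def fit_interval(sf: StructureFactor, window_bins: int = 3,
                 skip_bins: int = 1) -> float:
    """Fit a Gaussian around the interior S(q) peak; return 2*pi/mu (µm).

    The first ``skip_bins`` bins (the q -> 0 forward-scattering region) are
    excluded from the peak search.  Raises ``ValueError`` when no interior
    local maximum exists (aperiodic pattern).
    """
    s = sf.s_values
    q = sf.q_bins
    if len(s) < skip_bins + 3:
        raise ValueError("structure factor has too few bins for a peak fit")
    search = s.copy()
    search[:skip_bins] = -np.inf
    k = int(np.argmax(search))
    if k >= len(s) - 1:
        raise ValueError("no interior structure-factor peak: aperiodic pattern")
    background = float(np.median(s[skip_bins:]))
    is_local_max = (s[k] > s[k + 1]) and (k == skip_bins or s[k] > s[k - 1])
    if not is_local_max or s[k] <= 1.5 * background:
        raise ValueError("no interior structure-factor peak: aperiodic pattern")
    lo = max(0, k - window_bins)
    hi = min(len(s), k + window_bins + 1)
    p0 = (s[k] * np.sqrt(2 * np.pi) * sf.dq, q[k], sf.dq)
    bounds = ([0.0, max(q[lo], 1e-9), sf.dq / 10],
              [np.inf, q[hi - 1], (hi - lo) * sf.dq])
    try:
        popt, _ = curve_fit(_gauss, q[lo:hi], s[lo:hi], p0=p0,
                            bounds=bounds, maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"Gaussian peak fit failed: {exc}") from exc
    A, mu, sigma = popt
    sf.peak = (float(A), float(mu), float(abs(sigma)))
    return float(2 * np.pi / mu)


def image_interval(img_pixels: np.ndarray, pixel_pitch: float,
                   pad_factor: int = 4) -> float:
    """Pattern interval from the radially binned power spectrum of an image.

    The image route to the same quantity: peak of the angularly integrated
    |FFT|^2 (excluding the DC region), interval = 2*pi/q_peak via the same
    Gaussian fit.  A Hann window suppresses leakage from non-periodic
    boundaries and zero-padding refines the q sampling.
    """
    arr = np.asarray(img_pixels, float)
    arr = arr - arr.mean()
    ny, nx = arr.shape
    win = np.outer(np.hanning(ny), np.hanning(nx))
    Ny, Nx = ny * pad_factor, nx * pad_factor
    F = np.fft.fft2(arr * win, s=(Ny, Nx))
    power = (F * F.conj()).real
    fy = np.fft.fftfreq(Ny, d=pixel_pitch)
    fx = np.fft.fftfreq(Nx, d=pixel_pitch)
    qy, qx = np.meshgrid(2 * np.pi * fy, 2 * np.pi * fx, indexing="ij")
    qmag = np.hypot(qx, qy)
    dq = 2 * np.pi / (Ny * pixel_pitch)
    nbins = int(qmag.max() / dq / np.sqrt(2))
    which = np.round(qmag / dq).astype(int)
    valid = which < nbins
    sums = np.bincount(which[valid], weights=power[valid], minlength=nbins)
    counts = np.bincount(which[valid], minlength=nbins)
    s = sums / np.maximum(counts, 1)
    centers = np.arange(nbins) * dq
    sf = StructureFactor(centers, s, dq)
    # the Hann main lobe spans ~2 original bins; widen the fit accordingly
    return fit_interval(sf, window_bins=2 * pad_factor,
                        skip_bins=2 * pad_factor)
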