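"""Gradient structure-tensor orientation analysis.

The dominant direction of an image patch is the orientation of the eigen-axis
of the averaged 2x2 gradient structure tensor along which the intensity varies
least (the pattern axis, perpendicular to the dominant gradient), and the
coherency (lambda1 - lambda2) / (lambda1 + lambda2) measures how strongly the
pattern is aligned along it.  Coherency near 1 means strong alignment, near 0
no preferential orientation; in this system it doubles as a connectivity proxy
because isolated round clusters keep it low while fused cables raise it.

Angles are axial, folded to [0, 90] degrees with 0 = longitudinal (image x,
columns) and 90 = circumferential (image y, rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .render import DensityImage

#: default Gaussian-derivative scale (px) for the gradient operator
GRADIENT_SIGMA = 1.0

#: the circumferential-cable criterion
CABLE_DIRECTION_DEG = 75.0
CABLE_COHERENCY = 0.3


@dataclass
class OrientationResult:
    dominant_direction: float        # degrees in [0, 90]; NaN if undefined
    coherency: float                 # in [0, 1]
    orientation_histogram: np.ndarray | None = None  # weights over bin_edges
    bin_edges: np.ndarray | None = None
    median_orientation: float | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.dominant_direction)


def _as_array(img) -> np.ndarray:
    return img.pixels if isinstance(img, DensityImage) else np.asarray(img, float)


def fold_axial(theta_deg: np.ndarray | float):
    """Fold any angle (degrees, from the x axis) into axial [0, 90]."""
    t = np.mod(theta_deg, 180.0)
    return 90.0 - np.abs(90.0 - t)


def _gradients(arr: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    gy = gaussian_filter(arr, sigma, order=(1, 0), mode="nearest")
    gx = gaussian_filter(arr, sigma, order=(0, 1), mode="nearest")
    return gx, gy


def structure_tensor_summary(img, roi: tuple[int, int, int, int] | None = None,
                             sigma: float = GRADIENT_SIGMA
                             ) -> OrientationResult:
    """Dominant direction and coherency of one image patch.

    ``roi`` is (x, y, w, h) in pixels; default is the whole image.  A constant
    patch (zero gradients everywhere) yields coherency 0 and an undefined
    (NaN) direction.
    """
    arr = _as_array(img)
    gx, gy = _gradients(arr, sigma)
    if roi is not None:
        x, y, w, h = roi
        gx = gx[y:y + h, x:x + w]
        gy = gy[y:y + h, x:x + w]
    jxx = float(np.mean(gx * gx))
    jyy = float(np.mean(gy * gy))
    jxy = float(np.mean(gx * gy))
    trace = jxx + jyy
    if trace <= 0 or not np.isfinite(trace):
        return OrientationResult(np.nan, 0.0)
    root = np.hypot(jxx - jyy, 2 * jxy)
    coherency = root / trace
    if root == 0.0:
        # isotropic tensor: no dominant axis
        return OrientationResult(np.nan, 0.0)
    # major gradient axis angle; the pattern axis is perpendicular to it
    grad_angle = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    direction = fold_axial(grad_angle + 90.0)
    return OrientationResult(float(direction), float(coherency))


def cables_formed(frames, roi=None, sigma: float = GRADIENT_SIGMA,
                  direction_min: float = CABLE_DIRECTION_DEG,
                  coherency_min: float = CABLE_COHERENCY) -> int | None:
    """First frame index whose patch satisfies the circumferential-cable
    criterion (dominant direction > 75 degrees and coherency > 0.3), the
    anchor the time axis calls 0* min; ``None`` if never reached."""
    for k, frame in enumerate(frames):
        res = structure_tensor_summary(frame, roi, sigma)
        if (res.defined and res.dominant_direction > direction_min
                and res.coherency > coherency_min):
            return k
    return None


def orientation_distribution(img, sigma: float = GRADIENT_SIGMA,
                             window: float = 2.0,
                             bins: int = 90) -> tuple[np.ndarray, np.ndarray]:
    """Energy-weighted local-orientation histogram over axial [0, 90].

    The per-pixel structure tensor is smoothed with a Gaussian window before
    the pointwise eigen-analysis; weights are the local gradient energy.
    Returns (weights, bin_edges); weights sum to 1 unless the image is flat.
    """
    arr = _as_array(img)
    gx, gy = _gradients(arr, sigma)
    jxx = gaussian_filter(gx * gx, window, mode="nearest")
    jyy = gaussian_filter(gy * gy, window, mode="nearest")
    jxy = gaussian_filter(gx * gy, window, mode="nearest")
    grad_angle = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    theta = fold_axial(grad_angle + 90.0)
    energy = jxx + jyy
    edges = np.linspace(0.0, 90.0, bins + 1)
    hist, _ = np.histogram(theta.ravel(), bins=edges, weights=energy.ravel())
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, edges


def median_orientation(imgs, rois=None, sigma: float = GRADIENT_SIGMA,
                       bins: int = 90) -> float:
    """Median of the ROI-averaged axial orientation distribution (degrees).

    ``imgs`` is one image or a sequence; ``rois`` an optional list of
    (x, y, w, h) applied to every image.  Per-ROI distributions are averaged
    and the median is read off the pooled distribution.
    """
    if isinstance(imgs, (DensityImage, np.ndarray)):
        imgs = [imgs]
    edges = np.linspace(0.0, 90.0, bins + 1)
    acc = np.zeros(bins)
    n = 0
    for img in imgs:
        arr = _as_array(img)
        patches = [arr] if rois is None else [
            arr[y:y + h, x:x + w] for (x, y, w, h) in rois]
        for patch in patches:
            hist, _ = orientation_distribution(patch, sigma=sigma, bins=bins)
            acc += hist
            n += 1
    if n == 0 or acc.sum() <= 0:
        return float("nan")
    cdf = np.cumsum(acc) / acc.sum()
    k = int(np.searchsorted(cdf, 0.5))
    # linear interpolation within the median bin
    c0 = cdf[k - 1] if k > 0 else 0.0
    frac = (0.5 - c0) / max(cdf[k] - c0, 1e-12)
    return float(edges[k] + frac * (edges[k + 1] - edges[k]))
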