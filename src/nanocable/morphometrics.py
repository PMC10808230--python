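"""Cluster binarization, ellipse morphometrics, skeletons, circular stats.

The binarization pipeline mirrors the reference ImageJ recipe: rolling-ball
background subtraction (r = 50 px), local Otsu thresholding in a disk of
radius 5 px, then a 3x3 median "despeckle" on the mask.  Connected components
of at least 0.01 µm² are fitted with moment-equivalent ellipses; components
with solidity below 0.7 are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import circmean
from skimage import measure, morphology
from skimage.filters import rank
from skimage.restoration import rolling_ball

from .orientation import fold_axial
from .render import DensityImage

MIN_AREA_UM2 = 0.01
MIN_SOLIDITY = 0.7
ROLLING_BALL_RADIUS = 50
LOCAL_OTSU_RADIUS = 5


@dataclass
class BinaryImage:
    mask: np.ndarray                 # bool
    pixel_pitch: float               # µm / px
    provenance: dict


@dataclass
class ClusterRecord:
    """Moment-equivalent ellipse descriptors of one connected component."""

    area: float          # µm²
    major: float         # µm, full major-axis length
    minor: float         # µm
    angle_axial: float   # degrees in [0, 90], 90 = circumferential
    circularity: float
    solidity: float
    centroid: tuple[float, float]    # (x, y) in µm

    @property
    def aspect_ratio(self) -> float:
        return self.major / self.minor if self.minor > 0 else np.inf


def _as_image(img) -> tuple[np.ndarray, float]:
    if isinstance(img, DensityImage):
        return img.pixels, img.pixel_pitch
    return np.asarray(img, float), 1.0


def binarize(img, pixel_pitch: float | None = None,
             rolling_ball_radius: int = ROLLING_BALL_RADIUS,
             local_otsu_radius: int = LOCAL_OTSU_RADIUS) -> BinaryImage:
    """Rolling ball -> local Otsu -> despeckle, as in the reference pipeline."""
    arr, pitch = _as_image(img)
    if pixel_pitch is not None:
        pitch = pixel_pitch
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        mask = np.zeros(arr.shape, bool)
    else:
        sub = arr - rolling_ball(arr, radius=rolling_ball_radius)
        lo, hi = float(sub.min()), float(sub.max())
        if hi <= lo:
            mask = np.zeros(arr.shape, bool)
        else:
            img8 = np.clip((sub - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
            thr = rank.otsu(img8, morphology.disk(local_otsu_radius))
            # inclusive comparison keeps flat bright plateaus (whose local
            # window is single-valued) as foreground; zero stays background
            mask = (img8 >= thr) & (img8 > 0)
            mask = ndi.median_filter(mask.astype(np.uint8), size=3).astype(bool)
    return BinaryImage(mask, pitch, {
        "rolling_ball_radius": rolling_ball_radius,
        "local_otsu_radius": local_otsu_radius,
    })


def _axial_angle_from_moments(region) -> float:
    """Axial major-axis angle (degrees from x, folded to [0, 90])."""
    mu = region.moments_central
    m00 = mu[0, 0]
    if m00 <= 0:
        return np.nan
    var_y = mu[2, 0] / m00   # rows
    var_x = mu[0, 2] / m00   # columns
    cov = mu[1, 1] / m00
    if var_x == var_y and cov == 0:
        return np.nan
    theta = 0.5 * np.degrees(np.arctan2(2 * cov, var_x - var_y))
    return float(fold_axial(theta))


def fit_clusters(binary: BinaryImage,
                 min_area_um2: float = MIN_AREA_UM2,
                 min_solidity: float = MIN_SOLIDITY) -> list[ClusterRecord]:
    """Ellipse-fit all connected components passing the size/solidity cuts."""
    pitch = binary.pixel_pitch
    labels = measure.label(binary.mask, connectivity=2)
    records: list[ClusterRecord] = []
    for region in measure.regionprops(labels):
        area = region.area * pitch ** 2
        if area < min_area_um2:
            continue
        solidity = float(region.solidity)
        if solidity < min_solidity:
            continue
        major = region.axis_major_length * pitch
        minor = region.axis_minor_length * pitch
        if minor <= 0:
            minor = pitch / np.sqrt(12.0)   # single-row degenerate component
        perim = region.perimeter * pitch
        circ = 4 * np.pi * area / perim ** 2 if perim > 0 else 1.0
        cy, cx = region.centroid
        records.append(ClusterRecord(
            area=area, major=major, minor=minor,
            angle_axial=_axial_angle_from_moments(region),
            circularity=min(1.0, float(circ)),
            solidity=min(1.0, solidity),
            centroid=(cx * pitch, cy * pitch)))
    return records


def angle_statistics(records_or_angles) -> dict:
    """Circular mean and median of axial angles (degrees in [0, 90]).

    Axial angles are doubled before circular averaging and halved back, the
    standard treatment of axial data.  A near-zero resultant (e.g. equal
    weights at 0 and 90 degrees, antipodal after doubling) leaves the mean
    undefined (NaN with ``mean_defined`` False).
    """
    if len(records_or_angles) == 0:
        raise ValueError("no clusters: angle statistics undefined")
    if isinstance(records_or_angles[0], ClusterRecord):
        angles = np.array([r.angle_axial for r in records_or_angles])
    else:
        angles = np.asarray(records_or_angles, float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("no defined cluster angles")
    doubled = np.radians(2.0 * angles)
    z = np.exp(1j * doubled)
    resultant = abs(np.mean(z))
    if resultant < 1e-9:
        mean = np.nan
        defined = False
    else:
        mean = np.degrees(circmean(doubled)) / 2.0
        defined = True
    # circular median on the doubled circle: the sample point minimizing the
    # summed circular distances (ties broken by the smaller angle)
    diffs = np.abs(np.angle(np.exp(1j * (doubled[:, None] - doubled[None, :]))))
    costs = diffs.sum(axis=1)
    median = float(np.sort(angles[costs == costs.min()])[0])
    return {
        "circular_mean": float(mean) if defined else np.nan,
        "mean_defined": defined,
        "circular_median": median,
        "resultant_length": float(resultant),
        "n": int(angles.size),
    }


def _prune_end_branches(skel: np.ndarray) -> np.ndarray:
    """Remove terminal branches (endpoint-to-junction paths).

    Components without junctions (simple paths or cycles) are kept whole.
    """
    skel = skel.copy()
    neighbors = np.ones((3, 3))
    neighbors[1, 1] = 0
    labels, n = ndi.label(skel, structure=np.ones((3, 3)))
    for lab in range(1, n + 1):
        comp = labels == lab
        deg = ndi.convolve(comp.astype(int), neighbors, mode="constant")
        if not np.any(comp & (deg >= 3)):
            continue   # no junction: keep the simple path/cycle
        work = comp.copy()
        while True:
            deg = ndi.convolve(work.astype(int), neighbors, mode="constant")
            ends = work & (deg <= 1)
            if not ends.any() or work.sum() <= 1:
                break
            work &= ~ends
        skel[comp & ~work] = False
    return skel


def _skeleton_component_length(comp: np.ndarray, pitch: float) -> float:
    """Total path length of one skeleton component: sum of unique 8-neighbor
    edges, diagonal steps weighted sqrt(2)."""
    ys, xs = np.nonzero(comp)
    pts = set(zip(ys.tolist(), xs.tolist()))
    length = 0.0
    for (y, x) in pts:
        for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
            if (y + dy, x + dx) in pts:
                length += np.hypot(dy, dx)
    return length * pitch


def skeleton_lengths(images, pixel_pitch: float | None = None,
                     prebinarized: bool = False) -> dict:
    """Mean over ROIs of the per-ROI maximum skeleton length (µm).

    Each image/ROI is binarized (unless ``prebinarized``), skeletonized,
    terminal branches are pruned, and the longest connected skeleton is
    measured; an empty mask contributes 0.
    """
    maxima = []
    for img in images:
        if prebinarized:
            mask = img.mask if isinstance(img, BinaryImage) else np.asarray(img, bool)
            pitch = (img.pixel_pitch if isinstance(img, BinaryImage)
                     else (pixel_pitch or 1.0))
        else:
            b = binarize(img, pixel_pitch=pixel_pitch)
            mask, pitch = b.mask, b.pixel_pitch
        if not mask.any():
            maxima.append(0.0)
            continue
        skel = morphology.skeletonize(mask)
        skel = _prune_end_branches(skel)
        labels, n = ndi.label(skel, structure=np.ones((3, 3)))
        best = 0.0
        for lab in range(1, n + 1):
            best = max(best, _skeleton_component_length(labels == lab, pitch))
        maxima.append(best)
    return {"per_roi_max": maxima,
            "mean_max_length": float(np.mean(maxima)) if maxima else np.nan}
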