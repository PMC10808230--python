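"""Time-lapse analyses: fusion stability, cluster motion anisotropy, PIV.

All three operate on binarized or raw frame sequences and are applied
identically to microscopy-like movies and rendered simulation output.
"Actin signal" at a pixel always means the binarized mask value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from skimage.transform import resize

from .morphometrics import BinaryImage, binarize, fit_clusters
from .orientation import fold_axial
from .render import DensityImage
from .stats import TestResult
from scipy import stats as sps

FUSION_HORIZON = 11          # frames tracked past birth
FUSION_MAINTAIN = 0.8        # fraction of boundary pixels that must stay on
MIN_BOUNDARY_PIXELS = 5      # "more than 4 pixels"
ORIENTATION_BINS = ((0, 30), (30, 60), (60, 90))


@dataclass
class FusionEvent:
    birth_frame: int
    boundary_pixels: np.ndarray      # (k, 2) array of (row, col)
    boundary_axis_deg: float         # axial angle of the boundary's long axis
    orientation_deg: float           # axial fusion direction: perpendicular
                                     # to the boundary, 90 = circumferential
    orientation_bin: str             # "0-30" | "30-60" | "60-90"
    duration_frames: int             # consecutive maintained frames, <= 11
    censored: bool = False           # movie ended before the horizon


@dataclass
class ClusterTrackStep:
    frame: int
    delta_x: float                   # µm
    delta_y: float


@dataclass
class VelocityField:
    vx: np.ndarray                   # nm/s per interrogation window
    vy: np.ndarray
    valid: np.ndarray                # bool
    window_um: float
    frame_index: int = 0


def _ensure_masks(movie, pixel_pitch=None):
    """Binarize raw frames; pass through pre-binarized ones."""
    masks, pitch = [], pixel_pitch or 1.0
    for frame in movie:
        if isinstance(frame, BinaryImage):
            masks.append(frame.mask)
            pitch = frame.pixel_pitch
        elif isinstance(frame, DensityImage):
            b = binarize(frame)
            masks.append(b.mask)
            pitch = b.pixel_pitch
        else:
            arr = np.asarray(frame)
            if arr.dtype == bool:
                masks.append(arr)
            else:
                b = binarize(arr, pixel_pitch=pitch)
                masks.append(b.mask)
    return masks, pitch


def _watershed_boundaries(mask: np.ndarray) -> list[np.ndarray]:
    """Constriction boundaries inside a mask via distance-transform watershed.

    Returns a list of (k, 2) pixel-coordinate arrays, one per connected
    watershed-line component interior to the mask.
    """
    if not mask.any():
        return []
    dist = ndi.distance_transform_edt(mask)
    # light smoothing removes pixelation plateaus that would over-seed the
    # watershed and split one constriction into parallel lines
    smooth = ndi.gaussian_filter(dist, 1.0)
    peaks = peak_local_max(smooth, labels=mask, min_distance=3,
                           exclude_border=False)
    if len(peaks) < 2:
        return []
    markers = np.zeros(mask.shape, int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smooth, markers, mask=mask, watershed_line=True)
    line = mask & (labels == 0)
    if not line.any():
        return []
    comp, n = ndi.label(line, structure=np.ones((3, 3)))
    return [np.argwhere(comp == k) for k in range(1, n + 1)]


def _boundary_orientation(pixels: np.ndarray) -> float:
    """Axial principal-axis angle (degrees from x) of a pixel set."""
    if len(pixels) < 2:
        return np.nan
    ys = pixels[:, 0].astype(float)
    xs = pixels[:, 1].astype(float)
    cov = np.cov(np.stack([xs, ys]))
    theta = 0.5 * np.degrees(np.arctan2(2 * cov[0, 1],
                                        cov[0, 0] - cov[1, 1]))
    return float(fold_axial(theta))


def _bin_label(angle: float) -> str:
    for lo, hi in ORIENTATION_BINS:
        if lo <= angle <= hi and (angle < hi or hi == 90):
            return f"{lo}-{hi}"
    return "undefined"


def track_fusion(movie, pixel_pitch=None,
                 horizon: int = FUSION_HORIZON,
                 maintain_fraction: float = FUSION_MAINTAIN,
                 min_pixels: int = MIN_BOUNDARY_PIXELS) -> list[FusionEvent]:
    """Detect new inter-cluster boundaries and score their persistence.

    Per frame t, the watershed constriction lines of the mask with at least
    ``min_pixels`` pixels are candidate fusion sites; a site is newly formed
    iff its boundary pixels carried no actin signal at t-1.  The duration is
    the number of consecutive frames from birth (capped at ``horizon``) in
    which at least 80% of the boundary pixels remain on; events too close to
    the end of the movie are right-censored and flagged.
    """
    masks, _ = _ensure_masks(movie, pixel_pitch)
    events: list[FusionEvent] = []
    for t in range(1, len(masks)):
        for pixels in _watershed_boundaries(masks[t]):
            if len(pixels) < min_pixels:
                continue
            prev_on = masks[t - 1][pixels[:, 0], pixels[:, 1]]
            if prev_on.any():
                continue          # boundary already inside actin: not new
            duration = 1          # birth frame itself carries full signal
            censored = False
            for dt in range(1, horizon):
                if t + dt >= len(masks):
                    censored = True
                    break
                frac = masks[t + dt][pixels[:, 0], pixels[:, 1]].mean()
                if frac >= maintain_fraction:
                    duration += 1
                else:
                    break
            boundary_axis = _boundary_orientation(pixels)
            # a fusion along y leaves a boundary line along x: the fusion
            # direction is perpendicular to the boundary axis
            angle = fold_axial(boundary_axis + 90.0)
            events.append(FusionEvent(
                birth_frame=t, boundary_pixels=pixels,
                boundary_axis_deg=boundary_axis,
                orientation_deg=angle, orientation_bin=_bin_label(angle),
                duration_frames=duration, censored=censored))
    return events


def fusion_durations_by_bin(events) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {f"{lo}-{hi}": [] for lo, hi in ORIENTATION_BINS}
    for e in events:
        if e.orientation_bin in out:
            out[e.orientation_bin].append(e.duration_frames)
    return out


# cluster selection filters for motion analysis
MOTION_AREA_RANGE = (0.01, 0.1)       # µm²
MOTION_CIRCULARITY_RANGE = (0.5, 1.0)
MOTION_SIZE_RATIO = (0.5, 2.0)


def _labeled_clusters(mask: np.ndarray):
    labels, _ = ndi.label(mask, structure=np.ones((3, 3)))
    return labels


def track_motion(movie, pixel_pitch=None,
                 area_range=MOTION_AREA_RANGE,
                 circularity_range=MOTION_CIRCULARITY_RANGE,
                 size_ratio=MOTION_SIZE_RATIO) -> dict:
    """Frame-to-frame matching of small round clusters; anisotropy ratio.

    At frame t, clusters within the stated area and circularity ranges are
    matched to the cluster at t+1 whose size is within [0.5, 2] fold and
    which overlaps by at least one pixel; ambiguity is resolved by largest
    overlap, then most similar size, else the step is skipped.  Returns the
    steps plus the ratio mean(|dy|) / mean(|dx|) (NaN when both means are 0).
    """
    masks, pitch = _ensure_masks(movie, pixel_pitch)
    steps: list[ClusterTrackStep] = []
    for t in range(len(masks) - 1):
        recs = fit_clusters(BinaryImage(masks[t], pitch, {}),
                            min_area_um2=0.0, min_solidity=0.0)
        labels_next = _labeled_clusters(masks[t + 1])
        props_next = {}
        for lab in np.unique(labels_next):
            if lab == 0:
                continue
            ys, xs = np.nonzero(labels_next == lab)
            props_next[lab] = (len(ys) * pitch ** 2,
                               (xs.mean() * pitch, ys.mean() * pitch))
        labels_now = _labeled_clusters(masks[t])
        recs_by_label = {}
        for r in recs:
            cx, cy = r.centroid
            lab = labels_now[int(round(cy / pitch)) % masks[t].shape[0],
                             int(round(cx / pitch)) % masks[t].shape[1]]
            if lab > 0:
                recs_by_label[lab] = r
        for lab, r in recs_by_label.items():
            if not (area_range[0] <= r.area <= area_range[1]):
                continue
            if not (circularity_range[0] <= r.circularity
                    <= circularity_range[1]):
                continue
            overlap_labels = labels_next[labels_now == lab]
            overlap_labels = overlap_labels[overlap_labels > 0]
            if overlap_labels.size == 0:
                continue
            cands = []
            for lab2 in np.unique(overlap_labels):
                area2, cent2 = props_next[lab2]
                ratio = area2 / r.area
                if size_ratio[0] <= ratio <= size_ratio[1]:
                    ov = int(np.sum(overlap_labels == lab2))
                    cands.append((ov, -abs(np.log(ratio)), lab2, cent2))
            if not cands:
                continue
            cands.sort(reverse=True)
            if len(cands) > 1 and cands[0][:2] == cands[1][:2]:
                continue            # unresolvable tie: skip, per contract
            _, _, lab2, cent2 = cands[0]
            steps.append(ClusterTrackStep(
                frame=t,
                delta_x=cent2[0] - r.centroid[0],
                delta_y=cent2[1] - r.centroid[1]))
    dx = np.array([s.delta_x for s in steps])
    dy = np.array([s.delta_y for s in steps])
    mean_ax = float(np.mean(np.abs(dx))) if dx.size else 0.0
    mean_ay = float(np.mean(np.abs(dy))) if dy.size else 0.0
    ratio = mean_ay / mean_ax if mean_ax > 0 else np.nan
    return {"steps": steps, "ratio": ratio,
            "mean_abs_dx": mean_ax, "mean_abs_dy": mean_ay,
            "n": len(steps)}


def simulation_cluster_motion(frames, pixel_pitch=None) -> dict:
    """track_motion on rendered simulation frames plus the |dx| vs |dy|
    two-sided t test used to report per-condition motion anisotropy."""
    res = track_motion(frames, pixel_pitch=pixel_pitch)
    dx = np.abs([s.delta_x for s in res["steps"]])
    dy = np.abs([s.delta_y for s in res["steps"]])
    if len(dx) >= 2:
        t, p = sps.ttest_ind(dx, dy)
        res["test"] = TestResult(float(t), float(p),
                                 "two-sided t (|dx| vs |dy|)",
                                 (len(dx), len(dy)))
    else:
        res["test"] = None
    return res


PIV_ENLARGE = 10
PIV_TIME_SUBDIVISIONS = 4
PIV_WINDOW = 91                      # px on the enlarged image
PIV_LENGTH_RATIO_LIMIT = 0.1


def _subframes(frames: list[np.ndarray], subdivisions: int) -> list[np.ndarray]:
    out = [frames[0]]
    for a, b in zip(frames[:-1], frames[1:]):
        for k in range(1, subdivisions + 1):
            w = k / subdivisions
            out.append((1 - w) * a + w * b)
    return out


def _window_displacement(win_a: np.ndarray, win_b: np.ndarray,
                         search_radius: float | None = None):
    """Overlap-normalized linear cross-correlation peak with parabolic
    sub-pixel refinement.

    Windows are zero-padded to twice their size so the correlation is linear
    rather than circular, and each lag is divided by its overlap area to
    remove the loss-of-pairs taper that biases broad peaks toward zero.  The
    peak search is restricted to ``search_radius`` (default: quarter window).
    Returns (dx, dy, peak_value) or None for a flat window.
    """
    n = win_a.shape[0]
    a = win_a - win_a.mean()
    b = win_b - win_b.mean()
    va, vb = (a * a).mean(), (b * b).mean()
    if va <= 0 or vb <= 0:
        return None
    if search_radius is None:
        search_radius = n / 4
    N = 2 * n
    corr = np.fft.ifft2(np.fft.fft2(b, s=(N, N))
                        * np.conj(np.fft.fft2(a, s=(N, N)))).real
    lags = np.r_[np.arange(0, n), np.arange(-n, 0)]
    overlap = np.maximum(n - np.abs(lags), 1)
    corr /= overlap[:, None] * overlap[None, :]
    within = (np.abs(lags)[:, None] <= search_radius) \
        & (np.abs(lags)[None, :] <= search_radius)
    masked = np.where(within, corr, -np.inf)
    iy, ix = np.unravel_index(np.argmax(masked), masked.shape)
    peak = corr[iy, ix]

    def refine(c_m, c_0, c_p):
        d = c_m - 2 * c_0 + c_p
        return 0.5 * (c_m - c_p) / d if d < 0 else 0.0

    dy = lags[iy] + refine(corr[(iy - 1) % N, ix], peak, corr[(iy + 1) % N, ix])
    dx = lags[ix] + refine(corr[iy, (ix - 1) % N], peak, corr[iy, (ix + 1) % N])
    return dx, dy, peak / np.sqrt(va * vb)


def piv(movie, pixel_pitch=None, frame_interval: float = 0.32,
        enlarge: int = PIV_ENLARGE,
        time_subdivisions: int = PIV_TIME_SUBDIVISIONS,
        window: int = PIV_WINDOW,
        length_ratio_limit: float = PIV_LENGTH_RATIO_LIMIT) -> dict:
    """Particle image velocimetry on a raw-intensity movie.

    Frames are enlarged ``enlarge``-fold (bilinear); each ``window``-px
    interrogation window (0.394 µm at the native 0.04325 µm pitch) of
    consecutive enlarged frames is matched by normalized circular
    cross-correlation with parabolic sub-pixel refinement.  The frame
    interval is then subdivided ``time_subdivisions``-fold: the velocity
    fields are emitted at the sub-interval cadence by linear interpolation
    between the per-frame-pair measurements (correlating linearly blended
    sub-frames directly is ill-posed because they share content, which locks
    the correlation peak at zero lag).  Vectors whose length exceeds
    ``length_ratio_limit`` times the window size are rejected (the validity
    filter), as are featureless windows.  Returns the VelocityFields and the
    overall mean |Vx|, |Vy| in nm/s.
    """
    frames = []
    pitch = pixel_pitch or 1.0
    for f in movie:
        if isinstance(f, DensityImage):
            frames.append(f.pixels.astype(float))
            pitch = f.pixel_pitch
        else:
            frames.append(np.asarray(f, float))
    if len(frames) < 2:
        raise ValueError("PIV needs at least two frames")
    big = [resize(f, (f.shape[0] * enlarge, f.shape[1] * enlarge),
                  order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True) for f in frames]
    um_per_px = pitch / enlarge
    H, W = big[0].shape
    ny, nx = H // window, W // window
    oy = (H - ny * window) // 2
    ox = (W - nx * window) // 2
    raw_fields = []
    for k in range(len(big) - 1):
        vx = np.zeros((ny, nx))
        vy = np.zeros((ny, nx))
        valid = np.zeros((ny, nx), bool)
        for j in range(ny):
            for i in range(nx):
                sl = (slice(oy + j * window, oy + (j + 1) * window),
                      slice(ox + i * window, ox + (i + 1) * window))
                out = _window_displacement(
                    big[k][sl], big[k + 1][sl],
                    search_radius=length_ratio_limit * window + 2)
                if out is None:
                    continue
                dx, dy, _ = out
                if np.hypot(dx, dy) > length_ratio_limit * window:
                    continue
                vx[j, i] = dx * um_per_px / frame_interval * 1e3   # nm/s
                vy[j, i] = dy * um_per_px / frame_interval * 1e3
                valid[j, i] = True
        raw_fields.append(VelocityField(vx, vy, valid, window * um_per_px, k))
    fields = []
    if time_subdivisions <= 1 or len(raw_fields) == 1:
        fields = raw_fields
    else:
        for k, (f0, f1) in enumerate(zip(raw_fields[:-1], raw_fields[1:])):
            for s in range(time_subdivisions):
                w = s / time_subdivisions
                valid = f0.valid & f1.valid
                fields.append(VelocityField(
                    (1 - w) * f0.vx + w * f1.vx,
                    (1 - w) * f0.vy + w * f1.vy,
                    valid, f0.window_um, k * time_subdivisions + s))
        fields.append(raw_fields[-1])
    vx_all = [np.abs(f.vx[f.valid]) for f in fields if f.valid.any()]
    vy_all = [np.abs(f.vy[f.valid]) for f in fields if f.valid.any()]
    mean_vx = float(np.mean(np.concatenate(vx_all))) if vx_all else np.nan
    mean_vy = float(np.mean(np.concatenate(vy_all))) if vy_all else np.nan
    return {"fields": fields, "mean_abs_vx": mean_vx, "mean_abs_vy": mean_vy,
            "window_um": window * um_per_px}
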