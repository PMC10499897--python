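"""Morphodynamics of migrating cells from segmented mask movies.

Operates on binary/label mask time-lapse movies (cell outline from a
membrane marker, optional WAVE2 patch masks) and extracts the per-frame
and per-movie metrics used to compare migratory phenotypes: spread
area, eccentricity, centroid speed, turn angle, leading-edge area and
length, WAVE2 patch statistics, cell-cell contact extent, and the
WAVE2 fold-change around contact onset.

Conventions: connected components are 8-connected; perimeters are
pixels 4-adjacent to background; the image border counts as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "MaskMovie",
    "FrameMetrics",
    "LeadingEdgeRecord",
    "ContactRecord",
    "frame_metrics",
    "turn_angles",
    "speed",
    "leading_edge",
    "wave2_patch_stats",
    "contact_metrics",
    "contact_duration",
    "wave2_fold_change",
    "analyze_movie",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class MaskMovie:
    """Segmented time-lapse movie.

    Attributes
    ----------
    frames : (T, H, W) integer ndarray
        Label masks; 0 = background, 1..k = cells.
    wave2 : (T, H, W) bool ndarray or None
        Optional WAVE2 patch masks.
    frame_interval : float, seconds (5 s by convention).
    pixel_size : float, um/px.
    """

    frames: np.ndarray
    wave2: np.ndarray | None = None
    frame_interval: float = 5.0
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.wave2 is not None:
            self.wave2 = np.asarray(self.wave2).astype(bool)
            if self.wave2.shape != self.frames.shape:
                raise ValueError("wave2 must match frames shape")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class FrameMetrics:
    area_um2: float
    eccentricity: float
    centroid: np.ndarray  # (row, col) px
    perimeter_px: int


@dataclass
class LeadingEdgeRecord:
    le_area_um2: float
    le_area_px: int
    le_length_px: int
    n_clusters: int


@dataclass
class ContactRecord:
    contact_px: int
    contact_fraction: float  # % of the reference cell's perimeter
    perimeter_px: int


def perimeter_pixels(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` 4-adjacent to background (border = background)."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~interior


def frame_metrics(mask: np.ndarray, pixel_size: float) -> FrameMetrics:
    """Spread area, eccentricity, centroid and perimeter of one mask.

    Eccentricity is that of the ellipse with the same second central
    moments as the mask (0 = circular, ->1 = elongated).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    return FrameMetrics(
        area_um2=float(mask.sum()) * pixel_size**2,
        eccentricity=float(props.eccentricity),
        centroid=np.asarray(props.centroid, dtype=float),
        perimeter_px=int(perimeter_pixels(mask).sum()),
    )


def turn_angles(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Turn angle (deg) between successive displacement vectors.

    For three consecutive centroids c_{t-1}, c_t, c_{t+1} the turn
    angle is the angle between (c_t - c_{t-1}) and (c_{t+1} - c_t):
    0 deg = straight ahead, 180 deg = full reversal. Steps with zero
    displacement are skipped (NaN) and flagged.

    Returns
    -------
    (angles_deg, used) : ((T-2,) float ndarray, (T-2,) bool ndarray)
    """
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or len(c) < 3:
        raise ValueError("need >= 3 centroids of shape (T, 2)")
    v = np.diff(c, axis=0)
    norms = np.linalg.norm(v, axis=1)
    n_angles = len(c) - 2
    angles = np.full(n_angles, np.nan)
    used = np.zeros(n_angles, dtype=bool)
    for t in range(n_angles):
        if norms[t] == 0 or norms[t + 1] == 0:
            continue
        cosang = np.dot(v[t], v[t + 1]) / (norms[t] * norms[t + 1])
        angles[t] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        used[t] = True
    if not used.any():
        warnings.warn("all steps stationary; no turn angles", stacklevel=2)
    return angles, used


def speed(
    centroids: np.ndarray, frame_interval: float, pixel_size: float
) -> tuple[np.ndarray, float]:
    """Per-step and mean centroid speed in um/min."""
    c = np.asarray(centroids, dtype=float)
    if len(c) < 2:
        raise ValueError("need >= 2 centroids")
    step_px = np.linalg.norm(np.diff(c, axis=0), axis=1)
    per_step = step_px * pixel_size / frame_interval * 60.0
    return per_step, float(per_step.mean())


def leading_edge(
    mask_t: np.ndarray,
    mask_t1: np.ndarray,
    wave2_t1: np.ndarray,
    pixel_size: float,
) -> LeadingEdgeRecord:
    """Leading edge between two consecutive frames.

    The leading edge is the area gained between frames
    (``mask_t1 & ~mask_t``), keeping only 8-connected gained clusters
    that contain at least one WAVE2 pixel. Its length is the number of
    retained pixels 4-adjacent to the background of the later mask
    (the outside perimeter; the image border counts as background).
    """
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    wave2_t1 = np.asarray(wave2_t1, dtype=bool)
    gained = mask_t1 & ~mask_t
    labels, n = ndimage.label(gained, structure=_SQUARE3)
    retained = np.zeros_like(gained)
    n_kept = 0
    for lab in range(1, n + 1):
        cluster = labels == lab
        if (cluster & wave2_t1).any():
            retained |= cluster
            n_kept += 1
    outside = ~mask_t1
    # 4-neighbours touching background, border padded as background
    near_bg = ~ndimage.binary_erosion(~outside, structure=_CROSS, border_value=0)
    edge = retained & near_bg
    le_px = int(retained.sum())
    return LeadingEdgeRecord(
        le_area_um2=le_px * pixel_size**2,
        le_area_px=le_px,
        le_length_px=int(edge.sum()),
        n_clusters=n_kept,
    )


def wave2_patch_stats(
    wave2_mask: np.ndarray, pixel_size: float
) -> tuple[float, np.ndarray, int]:
    """Total WAVE2 area (um^2), per-patch areas (um^2) and patch count."""
    mask = np.asarray(wave2_mask, dtype=bool)
    labels = cc_label(mask, connectivity=2)
    n = labels.max()
    sizes = np.array(
        [np.count_nonzero(labels == lab) for lab in range(1, n + 1)], dtype=float
    )
    areas = sizes * pixel_size**2
    return float(mask.sum() * pixel_size**2), areas, int(n)


def contact_metrics(mask_a: np.ndarray, mask_b: np.ndarray) -> ContactRecord:
    """Cell-cell contact of cell A with cell B in one frame.

    The contact is the intersection of A's perimeter with the 1-px
    dilated perimeter of B (label masks abut without overlapping, so a
    strict intersection would be empty). The contact fraction is the
    percentage of A's perimeter in contact.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if (mask_a & mask_b).any():
        warnings.warn("masks overlap; contact evaluated on the overlap boundary",
                      stacklevel=2)
    per_a = perimeter_pixels(mask_a)
    per_b = perimeter_pixels(mask_b)
    contact = per_a & ndimage.binary_dilation(per_b, structure=_SQUARE3)
    n_per = int(per_a.sum())
    n_contact = int(contact.sum())
    fraction = 100.0 * n_contact / n_per if n_per else 0.0
    return ContactRecord(contact_px=n_contact, contact_fraction=fraction,
                         perimeter_px=n_per)


def contact_duration(contact_px_series) -> int:
    """Longest run of consecutive frames with nonzero contact."""
    best = run = 0
    for c in contact_px_series:
        run = run + 1 if c > 0 else 0
        best = max(best, run)
    return best


def wave2_fold_change(
    wave2_area_series, contact_onset: int, window: int = 6
) -> float:
    """WAVE2 fold-change around contact onset.

    Ratio of the mean total WAVE2 patch area over ``window`` frames
    starting at the onset frame to the mean over the ``window`` frames
    before it. 1.0 means the total patch area is conserved (e.g. pure
    relocation away from the contact).
    """
    areas = np.asarray(wave2_area_series, dtype=float)
    if contact_onset - window < 0 or contact_onset + window > len(areas):
        raise ValueError("onset must have `window` frames on both sides")
    pre = areas[contact_onset - window:contact_onset].mean()
    post = areas[contact_onset:contact_onset + window].mean()
    if pre == 0:
        raise ValueError("zero pre-contact WAVE2 area; fold change undefined")
    return float(post / pre)


def analyze_movie(movie: MaskMovie, cell_label: int = 1) -> tuple[pd.DataFrame, dict]:
    """Per-frame metrics table and per-movie summary for one cell.

    Returns a DataFrame with one row per frame (area, eccentricity,
    centroid, speed, turn angle, leading edge, WAVE2 and contact
    metrics where applicable) and a dict of per-movie means, matching
    the convention of averaging each time-lapse movie into one sample.
    """
    T = movie.n_frames
    cell = movie.frames == cell_label
    other_labels = sorted(set(np.unique(movie.frames)) - {0, cell_label})
    rows = []
    centroids = []
    for t in range(T):
        fm = frame_metrics(cell[t], movie.pixel_size)
        centroids.append(fm.centroid)
        row = {
            "frame": t,
            "area_um2": fm.area_um2,
            "eccentricity": fm.eccentricity,
            "centroid_row": fm.centroid[0],
            "centroid_col": fm.centroid[1],
            "perimeter_px": fm.perimeter_px,
        }
        if movie.wave2 is not None:
            total, sizes, n_patches = wave2_patch_stats(movie.wave2[t], movie.pixel_size)
            row.update(wave2_total_um2=total, wave2_n_patches=n_patches,
                       wave2_mean_patch_um2=float(sizes.mean()) if n_patches else 0.0)
            if t > 0:
                le = leading_edge(cell[t - 1], cell[t], movie.wave2[t], movie.pixel_size)
                row.update(le_area_um2=le.le_area_um2, le_length_px=le.le_length_px,
                           le_n_clusters=le.n_clusters)
        if other_labels:
            other = np.isin(movie.frames[t], other_labels)
            cr = contact_metrics(cell[t], other)
            row.update(contact_px=cr.contact_px, contact_fraction=cr.contact_fraction)
        rows.append(row)
    df = pd.DataFrame(rows)
    centroids = np.asarray(centroids)
    per_step, mean_speed = speed(centroids, movie.frame_interval, movie.pixel_size)
    df["speed_um_min"] = np.concatenate([[np.nan], per_step])
    angles, used = turn_angles(centroids)
    df["turn_angle_deg"] = np.concatenate([[np.nan], angles, [np.nan]])
    summary = {
        "mean_area_um2": float(df["area_um2"].mean()),
        "mean_eccentricity": float(df["eccentricity"].mean()),
        "mean_speed_um_min": mean_speed,
        "mean_turn_angle_deg": float(np.nanmean(angles)) if used.any() else np.nan,
    }
    if movie.wave2 is not None:
        summary["mean_wave2_total_um2"] = float(df["wave2_total_um2"].mean())
        if "le_area_um2" in df:
            summary["mean_le_area_um2"] = float(df["le_area_um2"].mean())
            summary["mean_le_length_px"] = float(df["le_length_px"].mean())
    if other_labels:
        summary["mean_contact_fraction"] = float(df["contact_fraction"].mean())
        summary["contact_duration_frames"] = contact_duration(df["contact_px"])
    return df, summary
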