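"""Axial protein-vs-membrane localization from two-channel z-stacks.

Two complementary analyses of where a membrane-associated protein sits
relative to the plasma membrane along the optical axis:

* ``pcc_by_plane`` — per-z-plane Pearson correlation of the two
  channels inside an Otsu mask of the reference channel, binned along z
  (confocal colocalization vs height).

* The z-line pipeline — at every lateral pixel the intensity-vs-z
  profile ("z-line") of the membrane channel shows two peaks (bottom
  and top plasma membrane). Lines are split into bottom/top halves,
  classified as in-ruffle or off-ruffle from a ridge-segmented maximum
  intensity projection, thickness-matched between groups, and the
  protein-to-membrane axial distance is estimated by bootstrap
  averaging of many z-lines: each half is oriented from the cell
  exterior inward, resampled profiles are averaged and renormalized,
  and the distance between the 20%-rise positions of the two channels
  is read off. Positive distance = protein displaced toward the cell
  interior relative to the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import pearsonr
from skimage.filters import meijering, threshold_otsu

__all__ = [
    "TwoChannelStack",
    "ZLineHalf",
    "DistanceEstimate",
    "pcc_by_plane",
    "segment_ruffles_mip",
    "extract_and_classify",
    "thickness_match_subsample",
    "bootstrap_distance",
]


@dataclass
class TwoChannelStack:
    """Membrane + protein channel 3D arrays, (z, y, x)."""

    mem: np.ndarray
    prot: np.ndarray
    z_step: float  # um
    pixel_size: float = 0.1  # um/px

    def __post_init__(self) -> None:
        self.mem = np.asarray(self.mem, dtype=float)
        self.prot = np.asarray(self.prot, dtype=float)
        if self.mem.shape != self.prot.shape or self.mem.ndim != 3:
            raise ValueError("channels must be equal-shape 3D arrays")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")


@dataclass
class ZLineHalf:
    """One membrane half of a z-line, oriented exterior -> interior.

    ``mem``/``prot`` are intensity samples at z_step spacing starting on
    the cell-exterior side; ``peak_index`` marks the membrane peak.
    """

    mem: np.ndarray
    prot: np.ndarray
    peak_index: int
    thickness: float  # um, full-cell peak separation
    group: str  # "in-ruffle" | "off-ruffle"
    half: str  # "top" | "bottom"


@dataclass
class DistanceEstimate:
    """Bootstrap distribution of the protein-membrane axial distance."""

    distances: np.ndarray  # um, one per successful resample
    mean: float
    n_lines: int
    n_boot: int
    n_skipped: int
    seed: int | None = None


def pcc_by_plane(
    stack: TwoChannelStack,
    n_bins: int = 10,
    intensity_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-z-bin Pearson correlation of the two channels.

    Planes are ranked by summed membrane intensity and the brightest
    planes holding ``intensity_fraction`` of the total are kept. In
    each kept plane an Otsu mask of the membrane channel selects the
    pixels over which the PCC of the two channels is computed. Kept
    planes are assigned to ``n_bins`` equal z-bins; the per-bin mean
    PCC and its standard error are returned.
    """
    sums = stack.mem.sum(axis=(1, 2))
    order = np.argsort(sums)[::-1]
    cum = np.cumsum(sums[order])
    n_keep = int(np.searchsorted(cum, intensity_fraction * sums.sum()) + 1)
    planes = np.sort(order[:n_keep])
    if len(planes) < n_bins:
        raise ValueError(f"only {len(planes)} planes selected; need >= {n_bins}")
    pccs, zs = [], []
    for z in planes:
        mem_plane = stack.mem[z]
        if np.ptp(mem_plane) == 0:
            warnings.warn(f"plane {z}: constant membrane channel, dropped",
                          stacklevel=2)
            continue
        mask = mem_plane > threshold_otsu(mem_plane)
        a, b = mem_plane[mask], stack.prot[z][mask]
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(f"plane {z}: PCC undefined, dropped", stacklevel=2)
            continue
        pccs.append(pearsonr(a, b).statistic)
        zs.append(z)
    zs = np.asarray(zs)
    pccs = np.asarray(pccs)
    edges = np.linspace(zs.min(), zs.max() + 1, n_bins + 1)
    which = np.clip(np.digitize(zs, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = pccs[which == b]
        rows.append({
            "bin": b,
            "z_center_um": 0.5 * (edges[b] + edges[b + 1]) * stack.z_step,
            "mean_pcc": float(sel.mean()) if sel.size else np.nan,
            "sem_pcc": float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else np.nan,
            "n_planes": int(sel.size),
        })
    return pd.DataFrame(rows)


def segment_ruffles_mip(stack: TwoChannelStack, ridge_scales=(1, 2, 4)) -> np.ndarray:
    """Ruffle mask from the membrane-channel maximum intensity projection.

    MIP over z -> Meijering ridge filter -> Otsu threshold.
    """
    mip = stack.mem.max(axis=0)
    if np.ptp(mip) == 0:
        raise ValueError("constant MIP; cannot segment ruffles")
    response = meijering(mip, sigmas=list(ridge_scales), black_ridges=False)
    if np.ptp(response) == 0:
        raise ValueError("constant ridge response; cannot segment ruffles")
    return response > threshold_otsu(response)


def extract_and_classify(
    stack: TwoChannelStack,
    ruffle_mask: np.ndarray,
    roi: np.ndarray | None = None,
    peak_prominence: float = 0.2,
    peak_min_distance: int = 3,
    overlap_threshold: float = 0.5,
) -> tuple[list[ZLineHalf], dict]:
    """Extract usable z-line halves and label them in/off ruffle.

    At each ROI pixel the membrane z-line is normalized to its peak and
    its peaks detected; lines without exactly two membrane peaks are
    excluded. The line is split at the midpoint between peaks into a
    bottom and a top half, each oriented from the cell exterior inward.
    A half is kept only if the protein channel overlaps the membrane:
    overlap = sum(min(mem, prot)) / sum(mem) >= ``overlap_threshold``.

    Returns the kept halves and an exclusion-count dict satisfying
    kept_lines + excluded_n_peaks + total-line bookkeeping.
    """
    ruffle_mask = np.asarray(ruffle_mask, dtype=bool)
    nz, ny, nx = stack.mem.shape
    if ruffle_mask.shape != (ny, nx):
        raise ValueError("ruffle_mask must match the lateral stack shape")
    if roi is None:
        roi = np.ones((ny, nx), dtype=bool)
    counts = {"total_lines": 0, "excluded_n_peaks": 0,
              "excluded_low_overlap_halves": 0, "kept_halves": 0}
    halves: list[ZLineHalf] = []
    for y in range(ny):
        for x in range(nx):
            if not roi[y, x]:
                continue
            counts["total_lines"] += 1
            mem_line = stack.mem[:, y, x]
            prot_line = stack.prot[:, y, x]
            if mem_line.max() <= 0:
                counts["excluded_n_peaks"] += 1
                continue
            mem_n = mem_line / mem_line.max()
            prot_n = prot_line / prot_line.max() if prot_line.max() > 0 else prot_line
            peaks, _ = find_peaks(mem_n, prominence=peak_prominence,
                                  distance=peak_min_distance)
            if len(peaks) != 2:
                counts["excluded_n_peaks"] += 1
                continue
            z_bot, z_top = int(peaks[0]), int(peaks[1])
            thickness = (z_top - z_bot) * stack.z_step
            mid = (z_bot + z_top) // 2
            group = "in-ruffle" if ruffle_mask[y, x] else "off-ruffle"
            # bottom half: exterior at z = 0; top half: exterior at z = nz-1
            for half_name, mem_h, prot_h, peak_i in (
                ("bottom", mem_n[: mid + 1], prot_n[: mid + 1], z_bot),
                ("top", mem_n[mid:][::-1], prot_n[mid:][::-1], nz - 1 - z_top),
            ):
                denom = mem_h.sum()
                overlap = float(np.minimum(mem_h, prot_h).sum() / denom) if denom > 0 else 0.0
                if overlap < overlap_threshold:
                    counts["excluded_low_overlap_halves"] += 1
                    continue
                counts["kept_halves"] += 1
                halves.append(ZLineHalf(mem=mem_h.copy(), prot=prot_h.copy(),
                                        peak_index=peak_i, thickness=thickness,
                                        group=group, half=half_name))
    return halves, counts


def thickness_match_subsample(
    in_group: list[ZLineHalf],
    off_group: list[ZLineHalf],
    rng: np.random.Generator,
    bins: int | np.ndarray = 10,
) -> list[ZLineHalf]:
    """Subsample the off-ruffle group to match the in-ruffle thicknesses.

    Using shared bin edges over cell thickness, the off-ruffle group is
    randomly subsampled so that its thickness histogram is proportional
    to the in-ruffle one (the largest such subsample). Raises if an
    occupied in-ruffle bin has no off-ruffle lines.
    """
    t_in = np.array([p.thickness for p in in_group])
    t_off = np.array([p.thickness for p in off_group])
    if t_in.size == 0 or t_off.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.isscalar(bins):
        lo = min(t_in.min(), t_off.min())
        hi = max(t_in.max(), t_off.max())
        edges = np.linspace(lo, hi + 1e-9, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    n_b = len(edges) - 1
    bin_in = np.clip(np.digitize(t_in, edges) - 1, 0, n_b - 1)
    bin_off = np.clip(np.digitize(t_off, edges) - 1, 0, n_b - 1)
    counts_in = np.bincount(bin_in, minlength=n_b)
    counts_off = np.bincount(bin_off, minlength=n_b)
    occupied = counts_in > 0
    unsupported = occupied & (counts_off == 0)
    if unsupported.any():
        bad = [f"[{edges[i]:.3g}, {edges[i+1]:.3g})" for i in np.nonzero(unsupported)[0]]
        raise ValueError(f"off-ruffle group has no lines in thickness bin(s) {bad}")
    scale = np.min(counts_off[occupied] / counts_in[occupied])
    chosen: list[ZLineHalf] = []
    for b in np.nonzero(occupied)[0]:
        take = int(np.floor(scale * counts_in[b]))
        idx = np.nonzero(bin_off == b)[0]
        pick = rng.choice(idx, size=min(take, len(idx)), replace=False)
        chosen.extend(off_group[i] for i in pick)
    return chosen


def _first_crossing(profile: np.ndarray, level: float) -> float | None:
    """Index (fractional) of the first upward crossing of ``level``.

    Scans from the exterior end (index 0). Returns None if the profile
    starts at/above the level (no clean approach) or never reaches it.
    """
    if profile[0] >= level:
        return None
    above = np.nonzero(profile >= level)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    frac = (level - profile[i - 1]) / (profile[i] - profile[i - 1])
    return (i - 1) + frac


def bootstrap_distance(
    group: list[ZLineHalf],
    z_step: float,
    n_lines: int = 100,
    n_boot: int = 200,
    rng: np.random.Generator | int | None = None,
    level: float = 0.2,
) -> DistanceEstimate:
    """Protein-to-membrane axial distance by bootstrap z-line averaging.

    Per resample, ``n_lines`` halves are drawn with replacement,
    aligned on their membrane peak, averaged per channel, renormalized
    to peak 1, and the first positions where each channel rises through
    ``level`` (approached from the cell exterior, linear interpolation)
    are located. The distance is (protein crossing - membrane crossing)
    in um; positive means the protein sits toward the cell interior.
    Resamples in which a channel has no clean rise are skipped and
    counted.
    """
    if len(group) < n_lines:
        raise ValueError(f"group has {len(group)} lines; need >= {n_lines}")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = rng
        rng = np.random.default_rng(rng)
    n_before = min(p.peak_index for p in group)
    n_after = min(len(p.mem) - p.peak_index for p in group)
    mem_mat = np.stack([p.mem[p.peak_index - n_before: p.peak_index + n_after]
                        for p in group])
    prot_mat = np.stack([p.prot[p.peak_index - n_before: p.peak_index + n_after]
                         for p in group])
    distances = []
    n_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(group), size=n_lines)
        mem_avg = mem_mat[idx].mean(axis=0)
        prot_avg = prot_mat[idx].mean(axis=0)
        mem_avg = mem_avg / mem_avg.max()
        if prot_avg.max() <= 0:
            n_skipped += 1
            continue
        prot_avg = prot_avg / prot_avg.max()
        c_mem = _first_crossing(mem_avg, level)
        c_prot = _first_crossing(prot_avg, level)
        if c_mem is None or c_prot is None:
            n_skipped += 1
            continue
        distances.append((c_prot - c_mem) * z_step)
    distances = np.asarray(distances)
    mean = float(distances.mean()) if distances.size else np.nan
    return DistanceEstimate(distances=distances, mean=mean, n_lines=n_lines,
                            n_boot=n_boot, n_skipped=n_skipped,
                            seed=None if seed is None else int(seed))
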