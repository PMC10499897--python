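"""Seeded synthetic-data generators with stored ground truth.

Every input class consumed by the analysis modules can be generated
here with known, retrievable ground truth: membrane contours with
analytic curvature, quasi-periodic ridge textures, persistent-random-
walk mask movies with WAVE2 patches and scripted collisions, double-
membrane two-channel z-stacks with a planted axial offset, buckled-
surface bead clouds with a curvature-preferring tracer, and tether
force tables. All generators are deterministic given (seed, config):
a fresh ``numpy`` Generator is seeded per call and the seed is recorded
in the ground truth. Ground truth is carried alongside the data and is
never read by any analysis code path.

Default scales mirror the experimental regimes the generators emulate:
~0.1 um/px fluorescence pixels at 5 s frame intervals, 28.9 nm/px for
electron-microscopy ridge textures, and a ~60 x 30 nm periodic bead box.
Lengths are um unless a field is explicitly nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .buckle import BeadFrame
from .contour import ContourTrace
from .morphodynamics import MaskMovie
from .ruffles import RuffleField
from .zline import TwoChannelStack

__all__ = [
    "GroundTruth",
    "ContourConfig", "gen_contour",
    "RuffleConfig", "gen_ruffle_image",
    "MovieConfig", "gen_mask_movie",
    "ZStackConfig", "gen_zstack",
    "BuckleConfig", "gen_buckled_trajectory",
    "TetherConfig", "gen_tether_forces",
]


@dataclass
class GroundTruth:
    """Planted values for one generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------- contours

@dataclass
class ContourConfig:
    """Polar bump contour r(theta) = R + a sin(m theta)."""

    seed: int = 0
    radius_um: float = 10.0
    amplitude_um: float = 0.0
    n_lobes: int = 8
    n_points: int = 720
    noise_sd_um: float = 0.0
    pixel_size: float = 0.05  # um/px
    closed: bool = True


def _polar_curvature(radius, amplitude, m, theta):
    """Signed curvature of r = R + a sin(m theta), interior-fiducial sign.

    The standard polar-curve curvature (positive where the curve is
    convex outward) is negated so that protrusive/outward curvature is
    negative, matching the contour analysis convention.
    """
    r = radius + amplitude * np.sin(m * theta)
    rp = amplitude * m * np.cos(m * theta)
    rpp = -amplitude * m**2 * np.sin(m * theta)
    kappa = (r**2 + 2 * rp**2 - r * rpp) / (r**2 + rp**2) ** 1.5
    return -kappa


def gen_contour(config: ContourConfig) -> tuple[ContourTrace, GroundTruth]:
    """Closed membrane contour with analytically known curvature."""
    if config.radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if abs(config.amplitude_um) >= config.radius_um:
        raise ValueError("amplitude must be smaller than the base radius "
                         "(self-intersecting contour)")
    rng = np.random.default_rng(config.seed)
    theta = np.linspace(0, 2 * np.pi, config.n_points, endpoint=False)
    r = config.radius_um + config.amplitude_um * np.sin(config.n_lobes * theta)
    x_um = r * np.cos(theta)
    y_um = r * np.sin(theta)
    # shift into a positive pixel frame with the centroid as fiducial
    offset = config.radius_um + abs(config.amplitude_um) + 2.0
    pts = np.column_stack([x_um + offset, y_um + offset]) / config.pixel_size
    if config.noise_sd_um > 0:
        pts = pts + rng.normal(0, config.noise_sd_um / config.pixel_size,
                               size=pts.shape)
    fiducial = np.array([offset, offset]) / config.pixel_size
    trace = ContourTrace(points=pts, pixel_size=config.pixel_size,
                         fiducial=fiducial, closed=config.closed,
                         trace_id=f"synthetic-{config.seed}")
    kappa = _polar_curvature(config.radius_um, config.amplitude_um,
                             config.n_lobes, theta)
    gt = GroundTruth(kind="contour", seed=config.seed, params={
        "kappa_um_inv": kappa.tolist(),
        "theta": theta.tolist(),
        "radius_um": config.radius_um,
        "amplitude_um": config.amplitude_um,
        "n_lobes": config.n_lobes,
        "noise_sd_um": config.noise_sd_um,
    })
    return trace, gt


# ------------------------------------------------------------ ridge texture

@dataclass
class RuffleConfig:
    """Quasi-parallel ridge texture of period ``period_px``."""

    seed: int = 0
    period_px: float = 12.0
    shape: tuple[int, int] = (200, 200)
    ridge_sigma_frac: float = 0.15  # ridge Gaussian width as fraction of period
    wiggle_amp_px: float = 1.0
    wiggle_period_px: float = 60.0
    noise_sd: float = 0.05  # fraction of ridge contrast
    roi_margin_px: int = 4
    pixel_size: float = 0.0289  # um/px (electron-microscopy regime)


def gen_ruffle_image(config: RuffleConfig) -> tuple[RuffleField, GroundTruth]:
    """Striped ridge field with stored period; phase and noise are seeded."""
    if config.period_px < 3:
        raise ValueError("stripe period below resolvability (< 3 px)")
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    phase = rng.uniform(0, config.period_px)
    wiggle_phase = rng.uniform(0, 2 * np.pi)
    u = xx + config.wiggle_amp_px * np.sin(
        2 * np.pi * yy / config.wiggle_period_px + wiggle_phase)
    # distance to the nearest ridge centreline (ridges parallel to y)
    d = np.abs((u - phase + config.period_px / 2) % config.period_px
               - config.period_px / 2)
    sigma = config.ridge_sigma_frac * config.period_px
    image = np.exp(-(d**2) / (2 * sigma**2))
    if config.noise_sd > 0:
        image = image + rng.normal(0, config.noise_sd, size=image.shape)
    roi = np.zeros(config.shape, dtype=bool)
    m = config.roi_margin_px
    roi[m:h - m, m:w - m] = True
    fieldobj = RuffleField(image=image, roi=roi, pixel_size=config.pixel_size,
                           image_id=f"stripes-{config.seed}")
    gt = GroundTruth(kind="ruffle_image", seed=config.seed, params={
        "period_px": config.period_px,
        "period_um": config.period_px * config.pixel_size,
        "phase_px": phase,
        "noise_sd": config.noise_sd,
    })
    return fieldobj, gt


# ------------------------------------------------------------- mask movies

@dataclass
class MovieConfig:
    """Persistent-random-walk cell blob with a protruding front."""

    seed: int = 0
    n_frames: int = 30
    shape: tuple[int, int] = (400, 600)
    pixel_size: float = 0.1  # um/px
    frame_interval: float = 5.0  # s
    speed_um_min: float = 12.0
    angular_sd_deg: float = 15.0  # heading diffusion per frame
    radius_um: float = 6.0
    protrusion: bool = True
    wave2_patches: int = 3
    wave2_patch_radius_px: int = 4
    collision: bool = False


def _disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return (yy - center[0])**2 + (xx - center[1])**2 <= radius**2


def gen_mask_movie(config: MovieConfig) -> tuple[MaskMovie, GroundTruth]:
    """Label mask movie of one migrating cell (plus optional collider).

    The cell is a disk with a frontal protrusion following a persistent
    random walk: constant speed, heading diffusing with the configured
    angular SD per frame. WAVE2 patches are seeded in newly gained area.
    In collision mode a second cell approaches head-on; from the contact
    frame onward both masks are clipped at the midline so they abut with
    a flattened contact zone, and the (constant-area) WAVE2 patch
    relocates from the front to the contact-free rear.
    """
    if config.n_frames < 3:
        raise ValueError("need n_frames >= 3")
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    r_px = config.radius_um / config.pixel_size
    step_px = config.speed_um_min / 60.0 * config.frame_interval / config.pixel_size
    sd_rad = np.radians(config.angular_sd_deg)

    heading = 0.0  # toward +x (columns)
    pos = np.array([h / 2.0, w * 0.25])
    centroids_a = [pos.copy()]
    headings = [heading]
    for _ in range(config.n_frames - 1):
        if not config.collision and sd_rad > 0:
            heading += rng.normal(0, sd_rad)
        pos = pos + step_px * np.array([np.sin(heading), np.cos(heading)])
        centroids_a.append(pos.copy())
        headings.append(heading)
    centroids_a = np.asarray(centroids_a)

    margin = 1.6 * r_px
    inside = ((centroids_a[:, 0] > margin) & (centroids_a[:, 0] < h - margin)
              & (centroids_a[:, 1] > margin) & (centroids_a[:, 1] < w - margin))
    n_frames = config.n_frames
    if not inside.all():
        n_frames = int(np.argmin(inside))
        if n_frames < 3:
            raise ValueError("cell leaves the field of view immediately; "
                             "enlarge the field or slow the cell")
        warnings.warn(f"cell leaves the field of view; movie truncated to "
                      f"{n_frames} frames", stacklevel=2)
        centroids_a = centroids_a[:n_frames]
        headings = headings[:n_frames]

    contact_frame = None
    centroids_b = None
    if config.collision:
        # second cell approaches head-on at the same speed
        pos_b = np.array([h / 2.0, w * 0.75])
        centroids_b = [pos_b.copy()]
        for _ in range(n_frames - 1):
            pos_b = pos_b + step_px * np.array([0.0, -1.0])
            centroids_b.append(pos_b.copy())
        centroids_b = np.asarray(centroids_b)
        gaps = np.linalg.norm(centroids_a - centroids_b, axis=1)
        touching = np.nonzero(gaps <= 2 * r_px)[0]
        if touching.size:
            contact_frame = int(touching[0])
            # both cells stall at contact
            centroids_a[contact_frame:] = centroids_a[contact_frame]
            centroids_b[contact_frame:] = centroids_b[contact_frame]

    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    wave2 = np.zeros((n_frames, h, w), dtype=bool)
    patch_r = config.wave2_patch_radius_px
    for t in range(n_frames):
        ca = centroids_a[t]
        dirvec = np.array([np.sin(headings[t]), np.cos(headings[t])])
        mask_a = _disk_mask((h, w), ca, r_px)
        if config.protrusion:
            mask_a |= _disk_mask((h, w), ca + 0.7 * r_px * dirvec, 0.6 * r_px)
        if config.collision:
            mask_b = _disk_mask((h, w), centroids_b[t], r_px)
            if contact_frame is not None and t >= contact_frame:
                mid = 0.5 * (ca[1] + centroids_b[t][1])
                cols = np.arange(w)[None, :]
                mask_a &= cols <= mid
                mask_b &= cols > mid
            frames[t][mask_b] = 2
        frames[t][mask_a] = 1
        mask_a_now = frames[t] == 1
        if config.collision:
            # scripted constant-area patch: front before contact, rear after
            side = 1.0 if (contact_frame is None or t < contact_frame) else -1.0
            patch_c = ca + side * 0.5 * r_px * dirvec
            wave2[t] = _disk_mask((h, w), patch_c, patch_r)
        elif t > 0:
            gained = mask_a_now & ~(frames[t - 1] == 1)
            seeds = np.argwhere(gained)
            if seeds.size:
                pick = seeds[rng.integers(0, len(seeds), size=config.wave2_patches)]
                for sy, sx in pick:
                    wave2[t] |= _disk_mask((h, w), (sy, sx), patch_r) & mask_a_now

    movie = MaskMovie(frames=frames, wave2=wave2,
                      frame_interval=config.frame_interval,
                      pixel_size=config.pixel_size)
    gt = GroundTruth(kind="mask_movie", seed=config.seed, params={
        "speed_um_min": config.speed_um_min,
        "angular_sd_deg": config.angular_sd_deg,
        "centroids_px": centroids_a.tolist(),
        "headings_rad": list(map(float, headings)),
        "contact_frame": contact_frame,
        "n_frames": n_frames,
        "wave2_area_px": [int(wave2[t].sum()) for t in range(n_frames)],
    })
    return movie, gt


# ---------------------------------------------------------------- z-stacks

@dataclass
class ZStackConfig:
    """Double-membrane two-channel stack with a planted axial offset."""

    seed: int = 0
    shape_xy: tuple[int, int] = (48, 48)
    nz: int = 64
    z_step: float = 0.1  # um
    pixel_size: float = 0.1  # um/px
    delta_z_um: float = 0.2  # protein shift toward the interior
    sheet_sigma_um: float = 0.15
    bottom_um: float = 1.2
    thickness_um: float = 3.0
    thickness_jitter_um: float = 0.2  # smooth lateral thickness variation
    ruffle_extra_thickness_um: float = 0.6
    ruffle_period_px: int = 8
    ruffle_width_px: int = 2
    ruffle_brightness: float = 1.0  # extra membrane signal inside ruffles
    photons: float = 300.0  # 0 -> noiseless


def gen_zstack(config: ZStackConfig) -> tuple[TwoChannelStack, GroundTruth]:
    """Two Gaussian membrane sheets in z, protein shifted by +delta_z inward.

    The membrane channel has a bottom and a top sheet whose separation
    (cell thickness) varies laterally and is larger inside ruffle
    stripes; ruffles are also brighter so that they are visible in the
    maximum intensity projection. The protein channel shows the same
    sheets shifted by ``delta_z_um`` toward the cell interior on both
    membranes. Poisson-like shot noise is applied at ``photons`` scale.
    """
    if config.z_step <= 0:
        raise ValueError("z_step must be positive")
    if config.delta_z_um < 0:
        raise ValueError("delta_z_um must be >= 0")
    if config.delta_z_um > config.thickness_um / 2:
        raise ValueError("delta_z_um exceeds half the sheet separation")
    rng = np.random.default_rng(config.seed)
    ny, nx = config.shape_xy
    xx = np.arange(nx)[None, :] * np.ones((ny, 1))
    ruffle = (xx % config.ruffle_period_px) < config.ruffle_width_px
    smooth = ndimage.gaussian_filter(rng.normal(0, 1, size=(ny, nx)), 6)
    if smooth.std() > 0:
        smooth = smooth / smooth.std()
    thickness = (config.thickness_um
                 + config.ruffle_extra_thickness_um * ruffle
                 + config.thickness_jitter_um * smooth)
    z_bot = np.full((ny, nx), config.bottom_um)
    z_top = z_bot + thickness
    z = (np.arange(config.nz) * config.z_step)[:, None, None]
    amp = 1.0 + config.ruffle_brightness * ruffle
    sig = config.sheet_sigma_um

    def sheets(zb, zt):
        return amp * (np.exp(-(z - zb)**2 / (2 * sig**2))
                      + np.exp(-(z - zt)**2 / (2 * sig**2)))

    mem = sheets(z_bot, z_top)
    prot = sheets(z_bot + config.delta_z_um, z_top - config.delta_z_um)
    if config.photons > 0:
        mem = rng.poisson(mem * config.photons) / config.photons
        prot = rng.poisson(prot * config.photons) / config.photons
    stack = TwoChannelStack(mem=mem, prot=prot, z_step=config.z_step,
                            pixel_size=config.pixel_size)
    gt = GroundTruth(kind="zstack", seed=config.seed, params={
        "delta_z_um": config.delta_z_um,
        "ruffle_mask": ruffle.tolist(),
        "thickness_um": thickness.tolist(),
        "bottom_um": config.bottom_um,
        "photons": config.photons,
    })
    return stack, gt


# ------------------------------------------------------- buckled membranes

@dataclass
class BuckleConfig:
    """Bead cloud on a buckled surface with a curvature-seeking tracer."""

    seed: int = 0
    n_frames: int = 50
    n_beads: int = 5000
    box: tuple[float, float] = (58.9, 29.5)  # nm
    amplitude_nm: float = 2.0
    n_waves: int = 1  # cosine periods of the buckle along x
    leaflet_offset_nm: float = 2.0  # half bilayer thickness; 0 -> single sheet
    jitter_sd_nm: float = 0.3
    placement: str = "argmax"  # "argmax" | "boltzmann"
    beta: float = 0.0  # nm, Boltzmann weight exp(beta * H)


def _buckle_height(x, config: BuckleConfig):
    k = 2 * np.pi * config.n_waves / config.box[0]
    return config.amplitude_nm * np.cos(k * x)


def _buckle_mean_curvature(x, config: BuckleConfig):
    """Closed-form H of h = a cos(kx): H = h_xx / (2 (1 + h_x^2)^(3/2))."""
    a = config.amplitude_nm
    k = 2 * np.pi * config.n_waves / config.box[0]
    hx = -a * k * np.sin(k * x)
    hxx = -a * k**2 * np.cos(k * x)
    return hxx / (2 * (1 + hx**2) ** 1.5)


def gen_buckled_trajectory(config: BuckleConfig) -> tuple[list[BeadFrame], GroundTruth]:
    """Frames of beads on z = h(x, y) = a cos(2 pi n x / Lx) with a tracer.

    Beads are drawn uniformly in the periodic box on both leaflets
    (z = h +- leaflet offset) with isotropic jitter. The tracer (x, y)
    is placed at the argmax of the planted mean curvature H (the trough
    of the cosine for a > 0) or Boltzmann-sampled with weight
    exp(beta * H); beta = 0 gives uniform placement.
    """
    if config.box[0] <= 0 or config.box[1] <= 0:
        raise ValueError("box dims must be positive")
    if config.jitter_sd_nm >= abs(config.amplitude_nm):
        raise ValueError("jitter SD must be smaller than the buckle amplitude")
    if config.placement not in ("argmax", "boltzmann"):
        raise ValueError("placement must be 'argmax' or 'boltzmann'")
    rng = np.random.default_rng(config.seed)
    Lx, Ly = config.box
    x_grid = np.linspace(0, Lx, 512, endpoint=False)
    H_grid = _buckle_mean_curvature(x_grid, config)
    frames = []
    tracer_xs = []
    for t in range(config.n_frames):
        x = rng.uniform(0, Lx, config.n_beads)
        y = rng.uniform(0, Ly, config.n_beads)
        leaflet = rng.choice([-1.0, 1.0], size=config.n_beads)
        zc = _buckle_height(x, config) + leaflet * config.leaflet_offset_nm
        if config.jitter_sd_nm > 0:
            zc = zc + rng.normal(0, config.jitter_sd_nm, config.n_beads)
        if config.placement == "argmax":
            tx = x_grid[np.argmax(H_grid)]
        else:
            wgt = np.exp(config.beta * H_grid)
            tx = rng.choice(x_grid, p=wgt / wgt.sum())
        ty = rng.uniform(0, Ly)
        frames.append(BeadFrame(beads=np.column_stack([x, y, zc]),
                                tracer_xy=np.array([tx, ty]),
                                box=config.box, time_ns=float(t)))
        tracer_xs.append(float(tx))
    gt = GroundTruth(kind="buckled_trajectory", seed=config.seed, params={
        "amplitude_nm": config.amplitude_nm,
        "n_waves": config.n_waves,
        "placement": config.placement,
        "beta": config.beta,
        "max_H_nm_inv": float(H_grid.max()),
        "min_H_nm_inv": float(H_grid.min()),
        "tracer_x_nm": tracer_xs,
        "leaflet_offset_nm": config.leaflet_offset_nm,
    })
    return frames, gt


# ------------------------------------------------------------ tether forces

@dataclass
class TetherConfig:
    """Per-cell tether force tables for two (or more) groups.

    ``groups`` maps a label to (mean_pN, sd_pN, n_cells).
    """

    seed: int = 0
    groups: dict = field(default_factory=lambda: {
        "wt": (61.58, 10.0, 24),
        "snx33_ko": (75.25, 10.0, 26),
    })
    tethers_per_cell: int = 3


def gen_tether_forces(config: TetherConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Normal tether-force draws per cell; negative draws are resampled."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, (mean, sd, n_cells) in config.groups.items():
        if mean <= 0:
            raise ValueError(f"group {group}: mean force must be positive")
        for c in range(n_cells):
            for _ in range(config.tethers_per_cell):
                f = rng.normal(mean, sd)
                while f <= 0:  # physical forces are positive; redraw
                    f = rng.normal(mean, sd)
                rows.append({"cell_id": f"{group}_{c:03d}", "group": group,
                             "force_pN": f})
    table = pd.DataFrame(rows)
    gt = GroundTruth(kind="tether_forces", seed=config.seed, params={
        "groups": {g: {"mean_pN": m, "sd_pN": s, "n_cells": n}
                   for g, (m, s, n) in config.groups.items()},
        "tethers_per_cell": config.tethers_per_cell,
    })
    return table, gt
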