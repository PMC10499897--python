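"""Curvature preference of a membrane-bound tracer on a buckled bilayer.

A buckled (laterally compressed) bilayer presents a spectrum of
curvatures within one periodic box, so the positions a membrane-bound
protein samples over a trajectory report its curvature preference. Per
frame, a periodic 2D Fourier height field h(x, y) is fit to the lipid
phosphate bead positions by linear least squares; the mean curvature H
is evaluated from the Monge-patch shape operator,

    H = ((1 + h_y^2) h_xx - 2 h_x h_y h_xy + (1 + h_x^2) h_yy)
        / (2 (1 + h_x^2 + h_y^2)^(3/2)),

with analytic derivatives of the Fourier series (H > 0 where the
surface curves toward +z). H is sampled at the protein centre of mass
and at one randomly chosen bead per frame; the two distributions and
their means quantify the preference. H is computed in nm^-1 and
reported in um^-1 (x 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "BeadFrame",
    "HeightField",
    "CurvatureSamples",
    "PreferenceSummary",
    "fit_height_field",
    "mean_curvature",
    "sample_curvature_series",
    "preference_summary",
]


@dataclass
class BeadFrame:
    """Phosphate bead cloud + tracer position for one trajectory frame.

    Coordinates in nm; x and y are periodic over ``box = (Lx, Ly)``.
    """

    beads: np.ndarray  # (N, 3)
    tracer_xy: np.ndarray  # (2,)
    box: tuple[float, float]
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        self.tracer_xy = np.asarray(self.tracer_xy, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3 or len(self.beads) == 0:
            raise ValueError("beads must be a nonempty (N, 3) array")
        if self.box[0] <= 0 or self.box[1] <= 0:
            raise ValueError("box dims must be positive")
        self.tracer_xy = np.mod(self.tracer_xy, np.asarray(self.box))


@dataclass
class HeightField:
    """Periodic Fourier surface h(x, y) over a rectangular box.

    ``coeffs[p, q]`` weights f_p(x) g_q(y) where, per axis, the basis is
    {1, cos(2*pi*k u / L), sin(2*pi*k u / L)} for k = 1..order, in the
    order [1, cos_1, sin_1, cos_2, sin_2, ...] ((2*order+1) functions).
    """

    coeffs: np.ndarray  # (2M+1, 2M+1)
    box: tuple[float, float]
    order: int
    rms_residual: float = 0.0


def _basis(u: np.ndarray, length: float, order: int, deriv: int = 0) -> np.ndarray:
    """Values of the periodic basis (or its derivative) at points u."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.empty((len(u), 2 * order + 1))
    out[:, 0] = 1.0 if deriv == 0 else 0.0
    for k in range(1, order + 1):
        w = 2.0 * np.pi * k / length
        arg = w * u
        if deriv == 0:
            c, s = np.cos(arg), np.sin(arg)
        elif deriv == 1:
            c, s = -w * np.sin(arg), w * np.cos(arg)
        elif deriv == 2:
            c, s = -(w**2) * np.cos(arg), -(w**2) * np.sin(arg)
        else:
            raise ValueError("deriv must be 0, 1 or 2")
        out[:, 2 * k - 1] = c
        out[:, 2 * k] = s
    return out


def fit_height_field(frame: BeadFrame, order: int = 2) -> HeightField:
    """Least-squares periodic Fourier fit of z over the bead (x, y).

    Exact (zero residual) when the beads lie on a band-limited surface
    within the fit order; with beads from both leaflets (z = h +- t/2)
    the fit returns the bilayer midsurface h.
    """
    n_coef = (2 * order + 1) ** 2
    if len(frame.beads) < n_coef:
        raise ValueError(f"need >= {n_coef} beads for order {order}")
    x, y, z = frame.beads.T
    bx = _basis(x, frame.box[0], order)
    by = _basis(y, frame.box[1], order)
    design = np.einsum("ni,nj->nij", bx, by).reshape(len(x), n_coef)
    sol, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < n_coef:
        raise ValueError("rank-deficient design: degenerate bead layout")
    resid = z - design @ sol
    return HeightField(coeffs=sol.reshape(2 * order + 1, 2 * order + 1),
                       box=frame.box, order=order,
                       rms_residual=float(np.sqrt(np.mean(resid**2))))


def _partials(field: HeightField, x, y):
    """h and its first/second partial derivatives at (x, y)."""
    M, (Lx, Ly) = field.order, field.box
    bx0, bx1, bx2 = (_basis(x, Lx, M, d) for d in (0, 1, 2))
    by0, by1, by2 = (_basis(y, Ly, M, d) for d in (0, 1, 2))
    C = field.coeffs

    def comb(ax, ay):
        return np.einsum("ni,ij,nj->n", ax, C, ay)

    return (comb(bx0, by0), comb(bx1, by0), comb(bx0, by1),
            comb(bx2, by0), comb(bx0, by2), comb(bx1, by1))


def evaluate(field: HeightField, x, y) -> np.ndarray:
    """Surface height h(x, y)."""
    return _partials(field, x, y)[0]


def mean_curvature(field: HeightField, x, y):
    """Monge-patch mean curvature H(x, y) in nm^-1 (positive toward +z)."""
    _, hx, hy, hxx, hyy, hxy = _partials(field, x, y)
    num = (1 + hy**2) * hxx - 2 * hx * hy * hxy + (1 + hx**2) * hyy
    den = 2.0 * (1 + hx**2 + hy**2) ** 1.5
    H = num / den
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(H[0])
    return H


@dataclass
class CurvatureSamples:
    """Per-frame H at the tracer and at a random bead (nm^-1)."""

    h_tracer: np.ndarray
    h_random: np.ndarray
    times_ns: np.ndarray
    n_failed: int = 0
    seed: int | None = None


def sample_curvature_series(
    frames: list[BeadFrame],
    order: int = 2,
    rng: np.random.Generator | int | None = None,
) -> CurvatureSamples:
    """Fit each frame and sample H at the tracer and one random bead."""
    if not frames:
        raise ValueError("no frames")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = rng
        rng = np.random.default_rng(rng)
    h_tr, h_rd, times = [], [], []
    n_failed = 0
    for frame in frames:
        try:
            field = fit_height_field(frame, order=order)
        except ValueError:
            n_failed += 1
            continue
        h_tr.append(mean_curvature(field, frame.tracer_xy[0], frame.tracer_xy[1]))
        bead = frame.beads[rng.integers(0, len(frame.beads))]
        h_rd.append(mean_curvature(field, bead[0], bead[1]))
        times.append(frame.time_ns)
    return CurvatureSamples(h_tracer=np.asarray(h_tr), h_random=np.asarray(h_rd),
                            times_ns=np.asarray(times), n_failed=n_failed,
                            seed=None if seed is None else int(seed))


@dataclass
class PreferenceSummary:
    """Histograms, KDE curves and means of the two H distributions.

    ``*_um`` fields are in um^-1 (nm^-1 x 1000), the unit used for
    cell-scale curvature.
    """

    bin_edges_um: np.ndarray
    hist_tracer: np.ndarray
    hist_random: np.ndarray
    kde_grid_um: np.ndarray
    kde_tracer: np.ndarray
    kde_random: np.ndarray
    mean_tracer_um: float
    mean_random_um: float

    @property
    def delta_mean_um(self) -> float:
        return self.mean_tracer_um - self.mean_random_um


NM_TO_UM_INV = 1e3  # nm^-1 -> um^-1


def preference_summary(
    samples: CurvatureSamples,
    bandwidth: float | str | None = None,
    bins: int = 30,
) -> PreferenceSummary:
    """Probability histograms, Gaussian-KDE overlays and means."""
    tr = samples.h_tracer * NM_TO_UM_INV
    rd = samples.h_random * NM_TO_UM_INV
    if tr.size == 0 or rd.size == 0:
        raise ValueError("empty curvature samples")
    both = np.concatenate([tr, rd])
    edges = np.linspace(both.min(), both.max(), bins + 1)
    if edges[0] == edges[-1]:
        edges = np.linspace(edges[0] - 1.0, edges[0] + 1.0, bins + 1)
    hist_tr, _ = np.histogram(tr, bins=edges, density=True)
    hist_rd, _ = np.histogram(rd, bins=edges, density=True)
    grid = np.linspace(edges[0], edges[-1], 256)
    kde_tr = _kde_or_spike(tr, grid, bandwidth)
    kde_rd = _kde_or_spike(rd, grid, bandwidth)
    return PreferenceSummary(
        bin_edges_um=edges, hist_tracer=hist_tr, hist_random=hist_rd,
        kde_grid_um=grid, kde_tracer=kde_tr, kde_random=kde_rd,
        mean_tracer_um=float(tr.mean()), mean_random_um=float(rd.mean()),
    )


def _kde_or_spike(data: np.ndarray, grid: np.ndarray, bandwidth) -> np.ndarray:
    """Gaussian KDE, degrading gracefully for (near-)constant samples."""
    if data.size < 2 or np.ptp(data) == 0:
        out = np.zeros_like(grid)
        out[np.argmin(np.abs(grid - data.mean()))] = 1.0
        return out
    return gaussian_kde(data, bw_method=bandwidth)(grid)
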