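"""Signed curvature profiles along segmented membrane contours.

Curvature is measured by sliding a window of ``2*half_width + 1``
consecutive contour points along the trace and fitting a circle to each
window (Kasa algebraic least squares). The magnitude is the reciprocal
fitted radius converted to um^-1 via the pixel size. The sign is fixed
by an interior fiducial: if the fitted circle's centre lies on the same
side of the local tangent as the fiducial the membrane bulges away from
the cell (protrusive, "outward") and the curvature is negative;
otherwise the membrane is deflected toward the interior (invagination,
"inward") and the curvature is positive. A convex cell outline with an
interior fiducial therefore carries negative curvature everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContourTrace",
    "CurvatureProfile",
    "fit_circle",
    "signed_curvature_profile",
    "curvature_summary",
]

#: Fitted radii above this value (px) are treated as straight lines, kappa = 0.
COLLINEAR_RADIUS_PX = 1e6


@dataclass
class ContourTrace:
    """Ordered 2D membrane trace in pixel coordinates.

    Attributes
    ----------
    points : (N, 2) ndarray
        Ordered (x, y) contour points in px. Consecutive points distinct.
    pixel_size : float
        um per px.
    fiducial : (2,) ndarray
        A point on the cell-interior side, off the contour.
    closed : bool
        Whether the trace wraps around.
    trace_id : str
    """

    points: np.ndarray
    pixel_size: float
    fiducial: np.ndarray
    closed: bool = True
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.fiducial = np.asarray(self.fiducial, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        d = np.diff(self.points, axis=0)
        if np.any(np.all(d == 0, axis=1)):
            raise ValueError("consecutive contour points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CurvatureProfile:
    """Signed curvature per contour point, in um^-1."""

    kappa: np.ndarray
    half_width: int
    valid: np.ndarray
    trace_id: str = "trace"

    @property
    def kappa_valid(self) -> np.ndarray:
        return self.kappa[self.valid]


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle through 2D points.

    Solves the linear normal equations of x^2 + y^2 = 2ax + 2by + c;
    exact for noiseless co-circular points. Near-collinear windows
    return ``radius = inf`` as a sentinel for a straight segment.

    Returns
    -------
    (center, radius) : ((2,) ndarray, float)
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (N, 2)")
    if np.all(pts == pts[0]):
        raise ValueError("all points identical")
    x, y = pts[:, 0], pts[:, 1]
    # centre coordinates for conditioning
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    A = np.column_stack([2 * u, 2 * v, np.ones(len(u))])
    b = u**2 + v**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        return np.array([np.inf, np.inf]), np.inf
    a, bb, c = sol
    r2 = c + a**2 + bb**2
    if r2 <= 0 or not np.isfinite(r2):
        return np.array([np.inf, np.inf]), np.inf
    return np.array([a + mx, bb + my]), float(np.sqrt(r2))


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _window_indices(i: int, half_width: int, n: int, closed: bool) -> np.ndarray | None:
    lo, hi = i - half_width, i + half_width
    if closed:
        return np.arange(lo, hi + 1) % n
    if lo < 0 or hi >= n:
        return None
    return np.arange(lo, hi + 1)


def signed_curvature_profile(trace: ContourTrace, half_width: int) -> CurvatureProfile:
    """Sliding-window circle-fit curvature along a contour.

    Parameters
    ----------
    trace : ContourTrace
    half_width : int
        Window half-width w in points; the window holds 2w + 1 points.

    Returns
    -------
    CurvatureProfile
        kappa in um^-1 with the fiducial sign convention
        (outward/protrusive negative, inward positive). Open traces have
        the first and last w samples flagged invalid; closed traces wrap.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    n = len(trace)
    if n < 2 * half_width + 1:
        raise ValueError("trace shorter than the fitting window")
    pts = trace.points
    kappa = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        idx = _window_indices(i, half_width, n, trace.closed)
        if idx is None:
            continue
        valid[i] = True
        center, radius = fit_circle(pts[idx])
        if not np.isfinite(radius) or radius > COLLINEAR_RADIUS_PX:
            kappa[i] = 0.0
            continue
        # local tangent from the window neighbours of point i
        prev_pt = pts[(i - 1) % n] if trace.closed else pts[max(i - 1, 0)]
        next_pt = pts[(i + 1) % n] if trace.closed else pts[min(i + 1, n - 1)]
        tangent = next_pt - prev_pt
        side_center = _cross2(tangent, center - pts[i])
        side_fid = _cross2(tangent, trace.fiducial - pts[i])
        same_side = side_center * side_fid > 0
        sign = -1.0 if same_side else 1.0
        kappa[i] = sign / (radius * trace.pixel_size)
    return CurvatureProfile(kappa=kappa, half_width=half_width, valid=valid,
                            trace_id=trace.trace_id)


@dataclass
class CurvatureSummary:
    """Pooled |kappa| histogram and per-trace statistics."""

    hist: np.ndarray
    bin_edges: np.ndarray
    per_trace_mean_abs: dict = field(default_factory=dict)
    per_trace_mean_signed: dict = field(default_factory=dict)
    per_trace_sd: dict = field(default_factory=dict)
    pooled_mean_abs: float = np.nan
    pooled_mean_signed: float = np.nan
    pooled_sd: float = np.nan


def curvature_summary(profiles, bins=50) -> CurvatureSummary:
    """Summarise curvature profiles across cells/traces.

    Produces a normalised histogram of |kappa| pooled over all valid
    points, one mean |kappa| per trace (the per-cell data point used in
    group comparisons), plus the signed mean and the SD of the signed
    distribution — the SD shrinks when a membrane flattens, e.g. at
    cell-cell contacts.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    pooled = []
    summary = CurvatureSummary(hist=np.array([]), bin_edges=np.array([]))
    for p in profiles:
        k = p.kappa_valid
        if k.size == 0:
            raise ValueError(f"profile {p.trace_id} has no valid points")
        pooled.append(k)
        summary.per_trace_mean_abs[p.trace_id] = float(np.mean(np.abs(k)))
        summary.per_trace_mean_signed[p.trace_id] = float(np.mean(k))
        summary.per_trace_sd[p.trace_id] = float(np.std(k))
    allk = np.concatenate(pooled)
    summary.pooled_mean_abs = float(np.mean(np.abs(allk)))
    summary.pooled_mean_signed = float(np.mean(allk))
    summary.pooled_sd = float(np.std(allk))
    hist, edges = np.histogram(np.abs(allk), bins=bins, density=True)
    summary.hist, summary.bin_edges = hist, edges
    return summary
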