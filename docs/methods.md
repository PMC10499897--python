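# Methods

`curvesense` re-implements, as a tested library, the quantification
procedures used to characterize curvature sensing at the leading edge of
migrating immune-like cells: how curved the membrane is (contour
curvature, ruffle wavelength), how the cell and its WAVE2 actin-nucleation
patches move (mask-movie morphodynamics), where a curvature-sensing
protein sits relative to the membrane (axial colocalization), what
curvatures a membrane-bound tracer prefers on a buckled bilayer, and how
tether forces translate into membrane tension. Every analysis can be
exercised on seeded synthetic data with known ground truth; this note
records the models, parameter choices, and their limits.

## Contour curvature (`contour`)

A membrane trace is an ordered list of 2D points (px) with a pixel size
and an interior fiducial. A window of `2*half_width + 1` consecutive
points slides along the trace; each window is fit with an algebraic
least-squares circle (Kåsa normal equations, solved via `lstsq` on
mean-centred coordinates for conditioning). The Kåsa fit is linear,
iteration-free, and exact on noiseless arcs, which is all these short
windows need; Pratt/Taubin refinements matter only for large-noise,
small-arc regimes not reached here. Windows whose fitted radius exceeds
10⁶ px (or whose design matrix is rank-deficient) are treated as straight,
κ = 0, so output stays bounded.

Signed curvature: κ = ±1/(r·pixel_size) in μm⁻¹. The sign comes from a
tangent-side rule — if the fitted centre lies on the same side of the
local tangent as the interior fiducial, the membrane bulges away from the
cell (protrusive, *outward*) and κ < 0; otherwise the membrane is
deflected toward the interior (invagination, *inward*) and κ > 0. A convex
cell outline therefore reads negative everywhere. The sign depends only
on which side the fiducial lies, so reversing the traversal direction of
the trace leaves signed κ unchanged (tested). Open traces mark the `2w`
endpoint samples invalid; closed traces wrap the window.

Accuracy is limited by how much the true curvature varies *within* one
window: the estimate converges to the analytic curvature as the window
arc becomes small against the feature wavelength. The benchmark bump
contour (R = 10 μm, a = 2 μm, m = 8 lobes) meets the 5 % max-error bound
at half-width 5 when sampled at 1440 points/contour (~0.9 px spacing at
50 nm/px), a density comparable to a manual segmentation clicked at
every-other-pixel resolution. Default half-widths: 5 points (electron
microscopy sampling), 3 at coarser light-sheet sampling; both
configurable, as is whether per-cell summaries use |κ| over all valid
points (the default here).

## Effective ruffle wavelength (`ruffles`)

Ruffles in electron micrographs form quasi-parallel ridge textures. The
effective wavelength is defined as ROI area (px) divided by the
skeletonized ridge pixel count, times the pixel size — a mean ridge
spacing. Pipeline: median filter (disk radius 2 px) → Meijering
neuriteness filter → Otsu threshold computed over ROI pixels only (so
background outside the leading edge cannot bias it) → morphological
skeletonization → drop skeleton fragments shorter than 15 px.

Two choices deserve comment. Ridge-filter scales default to {2, 3} px:
with the ~29 nm SEM pixel, ridges are 2–10 px wide, and adding a 4 px
scale lets the response of *dense* textures (period ≈ 6 px) blur into a
plateau that Otsu then splits through the flanks, merging adjacent
ridges. The 15 px fragment filter removes noise specks that survive
thresholding; real ridges at these magnifications span many tens of
pixels. With these defaults the planted period is recovered within 10 %
across periods 6–30 px and additive noise up to 20 % of ridge contrast
(144 conditions tested). At the large-period end (~30 px in a ~190 px
ROI) the measure itself carries an irreducible ±1-ridge discretization
error of up to ~9 %, which is a property of the area/skeleton definition,
not of the implementation. Skeleton length is a pixel count (the measure's
definition), not a Euclidean path length. λ is reported both in px and μm.

## Mask-movie morphodynamics (`morphodynamics`)

Inputs are label-mask movies (cell IDs as label values; 5 s frame
interval, ~0.1 μm/px) with optional WAVE2 patch masks. Conventions,
fixed once for all metrics: connected components are 8-connected,
perimeters are mask pixels 4-adjacent to non-mask, and the image border
counts as background.

* **Shape**: area = pixel count · pixel_size²; eccentricity is that of
  the ellipse with matching second central moments (`regionprops`).
* **Motion**: per-step centroid speed in μm/min; the turn angle at frame
  t is the angle between successive displacement vectors of the centre
  of mass over three consecutive frames (0° straight, 180° reversal);
  zero-displacement steps are skipped and flagged.
* **Leading edge**: the area gained between consecutive frames,
  restricted to gained clusters containing at least one WAVE2 pixel; its
  length is the number of retained pixels 4-adjacent to the background
  of the later mask (the outside perimeter). The gained-only ("leading")
  direction is used; retraction is not part of the measure.
* **WAVE2 patches**: 8-connected components of the WAVE2 mask; total
  area, per-patch sizes, count.
* **Contacts**: the contact of cell A with cell B is the intersection of
  A's perimeter with the 1-px-dilated perimeter of B — label masks abut
  without overlapping, so a strict perimeter intersection would be
  empty. Contact fraction is the percentage of A's perimeter in contact;
  contact duration is the longest consecutive run of contact frames.
* **WAVE2 fold-change at contact**: ratio of mean total WAVE2 *mask
  area* over a window (default 6 frames = 30 s) starting at contact
  onset to the mean over the window before onset. Mask area rather than
  raw intensity keeps the measure independent of illumination; pure
  relocation of patches at constant total area gives 1.0 by
  construction. Window and quantity are configurable.

Per-movie summaries are means over frames, so each time-lapse movie
contributes one sample to group comparisons.

## Axial colocalization (`zline`)

**Per-plane PCC.** Planes of a two-channel confocal stack are ranked by
summed membrane intensity and the brightest planes holding 80 % of the
total are kept (a cumulative-sum reading of "top 80 % intensity"; the
fraction is configurable). Per plane, an Otsu mask of the membrane
channel selects pixels and the Pearson correlation of the two channels
is computed within it; planes with constant masked intensity are dropped
with a warning. Kept planes are assigned to 10 equal z-bins; per-bin
mean ± SEM is reported.

**Z-line distance.** At each lateral pixel the membrane intensity-vs-z
profile is normalized to its peak; lines without exactly two detected
membrane peaks (prominence ≥ 0.2 of the normalized scale, separation
≥ 3 z-samples — the data give no parameters, these are conventional
peak-finding settings) are excluded. Peak separation times z-step is the
local cell thickness. The line splits at the midpoint between peaks into
bottom and top halves, each re-oriented to run from the cell exterior
inward so both membranes share one sign convention. A half is kept only
if the protein overlaps the membrane profile: Σ min(mem, prot)/Σ mem ≥
0.5 by default. This filter encodes the assumption that the protein is
membrane-proximal; when benchmarking large planted offsets (≥ ~2 sheet
widths) it must be relaxed (0.1 in the recovery tests) or it correctly
rejects every line. Halves are labelled in-/off-ruffle from a ruffle
mask segmented on the membrane maximum-intensity projection (Meijering →
Otsu), and the off-ruffle group can be randomly subsampled to match the
in-ruffle thickness histogram (shared bin edges, largest proportional
subsample) so thickness does not confound the comparison.

The distance itself is estimated by bootstrap: per resample, 100 halves
drawn with replacement are aligned on their membrane peak, averaged per
channel, renormalized, and the first positions where each channel rises
through 20 % (approached from the exterior, linear interpolation between
z-samples) are located; the distance is protein crossing minus membrane
crossing, so *positive = protein displaced toward the cell interior*.
200 resamples give the distribution; resamples whose profile starts at
or above 20 % are skipped and counted. With the default synthetic stack
(48×48×64 voxels, 0.1 μm z-step, Poisson noise at 300 photons) planted
offsets of 0–0.2 μm are recovered to ~3 nm and 0.4 μm within one z-step.

## Buckled-membrane curvature preference (`buckle`)

A laterally compressed bilayer buckles into a periodic fold, exposing a
spectrum of curvatures in one box; where a membrane-bound protein sits
on that fold reports its curvature preference. Per frame, a periodic 2D
Fourier height field h(x, y) (tensor basis {1, cos, sin} per axis up to
order M) is fit to the phosphate-bead positions by linear least squares.
Beads of both leaflets are used, so the fitted surface is the bilayer
midsurface and the rms residual ≈ half the bilayer thickness; fitting a
single leaflet is a caller choice (pass that leaflet's beads).

Mean curvature comes from the Monge-patch shape operator with analytic
derivatives of the series:

    H = ((1+h_y²)h_xx − 2h_x h_y h_xy + (1+h_x²)h_yy) / (2(1+h_x²+h_y²)^{3/2})

with H > 0 where the surface curves toward +z. H is evaluated at the
protein centre of mass and at one uniformly drawn bead per frame; the
two series, their histograms, Gaussian-KDE overlays (SciPy's Scott-rule
bandwidth unless overridden) and means summarize the preference, in
μm⁻¹ (nm⁻¹ × 1000).

Fit order defaults to M = 2 per axis. The choice is driven by a
noise-amplification argument: curvature differentiates twice, so a
coefficient error at wavenumber k inflates by k². With realistic bead
clouds (~5000 phosphates in a 59×29 nm box, the Martini lipid density,
±2 nm leaflet offsets) an M = 6 fit lets leaflet/positional noise
dominate H completely (errors ~40× the buckle's own curvature), while
M = 2 resolves the fundamental buckle plus harmonics and recovers the
planted extremum within sampling error. Order is configurable for
strongly multi-modal surfaces. A related caveat governs validation
surfaces: only band-limited periodic surfaces are legitimate fixtures —
the truncated Fourier second derivative of a surface with slope kinks at
the box edge (e.g. a tiled spherical cap) does not converge pointwise.

## Tether tension (`mechanics`)

A membrane tether held at constant length equilibrates at the static
force F₀ with T = F₀²/(8Bπ²); B is the plasma-membrane bending rigidity,
taken as 2.7×10⁻¹⁹ N·m for all conditions. Forces in pN convert to N
before evaluation; T is reported in μN/m. Summaries follow the
measurement hierarchy (≥3 tether pulls per cell): tethers average within
cells, cells within groups. Because T is quadratic in F₀, converting
mean forces (the default, consistent with published force/tension pairs)
and averaging per-tether tensions differ by a Jensen gap; both modes are
provided.

## Synthetic data (`synthgen`)

Each generator is deterministic given (seed, config) — one fresh
`numpy` Generator per call, seed recorded — and returns its ground
truth alongside the data; analysis code never reads ground truth, and
generated data reach the analyses through the same file readers as real
data. Default scales mirror the experimental regimes: 0.1 μm/px and 5 s
frames for fluorescence movies, 28.9 nm/px ridge textures, 0.1 μm
z-steps, a ~59×29 nm bead box.

What the generators emulate — and what they do not:

* **Contours**: polar curves r(θ) = R + a·sin(mθ) with closed-form
  signed curvature; optional Gaussian point noise. No segmentation
  errors with spatial correlation.
* **Ridge textures**: Gaussian-profile ridges at a planted period with a
  gentle sinusoidal wiggle and additive noise. No branching, termination
  or curvature of real ruffle fields.
* **Mask movies**: a disk-plus-frontal-protrusion blob on a persistent
  random walk (constant speed 12 μm/min, heading diffusion 15°/frame,
  radius 6 μm) with WAVE2 patches seeded in newly gained area; a
  scripted head-on collision mode flattens both masks at the midline
  from the contact frame and relocates a constant-area WAVE2 patch from
  front to rear. No shape fluctuation, no segmentation noise, no
  realistic patch kinetics — the movies validate bookkeeping and
  kinematic recovery, not biology.
* **Z-stacks**: two Gaussian sheets (σ 0.15 μm) whose separation (3 μm
  base) is larger and brighter inside ruffle stripes, protein sheets
  shifted by Δz toward the interior on both membranes, Poisson noise.
  No lattice-light-sheet PSF anisotropy or deskew artefacts.
* **Bead clouds**: both-leaflet beads on a planted cosine buckle with
  jitter; tracer placed at the curvature argmax or Boltzmann-weighted
  (exp(βH)); β = 0 is the uniform control. No protein footprint or
  membrane response to the protein.
* **Tether tables**: per-tether normal draws around group means
  (negative draws resampled), ≥3 per cell.

Passing tests on these fixtures therefore demonstrates the correctness
of the estimators under their stated assumptions, not robustness to
every artefact of real microscopy (drift, bleaching, segmentation
failure modes), which remain the caller's responsibility.

## Problem sizes

Test and benchmark runs use contours of 720–1440 points, 200×200 px
textures, 25–30-frame movies at 400×600 px, 48×48×64 z-stacks with
100-line/200-resample bootstraps, and 25–50-frame bead trajectories of
5000 beads — sizes at which every pipeline completes in seconds while
the statistical tolerances above hold.

## Known limitations

* The contour sign rule assumes the fiducial is on the interior side of
  the local tangent; for strongly non-convex traces a single fiducial
  can sit on the wrong side of distant segments (an exterior fiducial
  demonstrably flips only the near arc). Use one fiducial per locally
  analyzed segment, as in manual practice.
* The wavelength measure undercounts by up to one ridge at periods
  approaching the ROI size (see above).
* The z-line pipeline assumes exactly two membrane crossings per line;
  folded membranes that triple-cross a z-column are excluded by design.
* `pcc_by_plane` treats the Otsu mask per plane independently; very
  sparse planes can be dropped entirely.
* The buckle analysis assumes the surface is single-valued over (x, y)
  (Monge patch) — overhangs that develop at extreme compression violate
  the model.
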