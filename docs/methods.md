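# Methods

This note documents the models behind `spheromet`: what the synthetic
generators emulate, how each measurement is defined, the numerical
choices that matter, and what the validation does and does not show.
Conventions throughout: array axes are `(frame, z, y, x)`, 0-based, voxel
centers at integer coordinates; lengths are in pixels unless a
calibration (µm/px laterally, µm per z-step, s per frame) is applied.

## Circularity and phase structure

Circularity is the form factor `4π·A/P²` of the projected silhouette
contour. For polygons this is exact (shoelace area, vertex-to-vertex
perimeter); a circle gives 1, a square π/4, a 3:1 rectangle 3π/16.

For binary masks the choice of perimeter estimator dominates the error
budget. Counting pixel edges overestimates a disc's perimeter by up to
~27% (taxicab limit) and biases circularity low, so contours are
extracted as subpixel iso-contours (marching squares at level 0.5).
Marching squares on a *raw* binary mask still inherits the staircase and
biases disc circularity low by ~11%; the mask is therefore Gaussian
pre-smoothed (default σ = 1.5 px) before contouring, after which a
radius-50 disc measures within ~0.3% of 1 and areas within 1%. The
smoothing rounds true corners slightly (a square mask reads ~0.80
instead of 0.785); for the smooth-boundary silhouettes this package
targets that bias is negligible. Holes are filled and only the largest
connected component is kept; masks of surface protrusions can optionally
be removed by a morphological opening (radius configurable, off by
default for circularity, 5 px for fusion axis measurements where
protrusions are explicitly not part of the body axis).

Phases are defined operationally, since flat/rising/flat is a
description, not an algorithm: the series is moving-median smoothed
(window 3 h), and the latent phase is the initial maximal run with
|slope| < 0.005 circularity/h; the static phase is the final such run
whose values also lie within 5% of the final plateau; rising is what
remains. Missing frames (empty masks) are flagged NaN and never
interpolated, so they cannot manufacture phase boundaries.

Jump detection flags forward differences that exceed both an absolute
floor (`min_step`, default 0.05) and 5× the median absolute deviation of
differences in a 15-frame local window. The MAD gate suppresses false
positives during a steep but smooth rise; the absolute floor suppresses
them in flat noise.

## Synthetic rounding movies

Silhouettes are drawn from the stadium family (a rectangle capped by two
semicircles; corner radius equals half the width). A stadium with
elongation `u = l/ρ` has circularity `c(u) = π(π+2u)/(π+u)²`, strictly
decreasing from 1, so any programmed circularity maps to a unique shape
and the generator can render an exact circularity-versus-time curve.
Area is conserved across frames (the mass rearranges, it does not grow)
and the orientation is a seeded random angle.

The programmed curve is flat at the analytic initial circularity until
`t_latent`, rises to `c_inf` by `t_static` (smoothstep by default, or a
rescaled logistic with steepness `k = 6` over the unit window — steeper
logistics have tails so flat that the phase boundary becomes genuinely
ill-defined at ±1 h resolution), and is flat afterwards. Fusion events
are modeled at the kinetics level: an instantaneous upward step of the
programmed amplitude, with the continuous rise shrunk by the total jump
so the curve stays monotone and ends at `c_inf`; the rendered silhouette
correspondingly shortens abruptly, the post-merger outline of the fused
mass. The generator does not render the two sub-masses separately before
the merger.

## Synthetic nuclei movies and motion models

Nuclei are anisotropic Gaussian blobs (default σ = (1.0, 2.7, 2.7) px in
z/y/x, matching the scale the default band-pass detector is tuned to)
plus additive Gaussian noise at a stated SNR (peak amplitude over noise
σ). Initial positions are placed by rejection sampling with a minimum
separation of 4×max(σ_psf) and per-axis borders of 3σ.

Motion is entity-based; every programmed step has exactly `step_scale`
magnitude so ground-truth directions are always defined:

* *independent_walk* — each cell is its own entity with a fresh uniform
  random direction per frame.
* *coherent_groups* — each group translates with a shared step;
  `coherence < 1` adds `(1−coherence)`-scaled individual noise. This is
  a deliberately minimal stand-in for sub-groups of cells folding as
  rigid arms: rigid translation reproduces the r ≈ +1 signature without
  simulating mechanics.
* *passing_pairs* — pair members step antiparallel (r = −1), the
  neighbor-exchange signature.
* *mixture* — cells are laid out in spatial pairs (member distance 1.2×
  the minimum separation, pair centers far enough that each cell's
  nearest neighbor is its partner); each pair is coherent with
  probability `mixture_weight`, else both members walk independently.
  This produces the bimodal r distribution (peak at +1 over a uniform
  background) and a coordinated fraction of `w + (1−w)·0.1` at
  r > 0.8.

Walls reflect steps jointly per entity (flip the offending component for
every member; drop it if both walls are hit), so perfect coherence and
antiparallelism survive the boundary exactly. Entities also carry a
hard-core exclusion distance (default 0.7× the minimum placement
separation): a step that would bring two entities closer is redrawn up
to ten times, then skipped. Nuclei are excluded-volume objects, and
without this a long random walk drifts cells into unresolvable contact,
which would make programmed identities meaningless. No division or death
occurs: trajectory count is constant, which matches short (~12 h)
imaging windows but not longer cultures.

What the generator does *not* emulate: Poisson photon statistics (noise
is additive Gaussian — the simplest model that stresses detection),
intensity variation between nuclei, bleaching, aberration, or motion
blur. Passing tests therefore validate the geometry and statistics of
the pipeline, not its robustness to every real-microscope artifact.

## Detection and linking

Detection is a band-pass blob search: Difference of Gaussians with
per-axis kernel pairs (defaults 1.9/3.8 px laterally, 0.7/1.4 px
axially; border mode reflect), local maxima above a threshold (default:
Otsu on the positive responses, recorded in the output), and greedy
suppression so no two detections lie within an anisotropic exclusion
radius (default 4 px lateral / 2 px axial, ellipsoidal norm; strongest
response wins). Subvoxel refinement is an iterative Gaussian-weighted
centroid of the positive band-pass response (window widths = the
geometric mean of the two DoG sigmas per axis, five iterations); unlike
a three-point parabola it uses the whole peak and is unbiased for
symmetric blobs away from the border. At SNR 5 this reaches ~0.12 px
lateral / ~0.05 px axial precision, which is at the Cramér–Rao limit for
these blob parameters — localization cannot be meaningfully improved
without more signal.

Linking considers consecutive frames only: candidate pairs within
`max_link_dist` are sorted by ascending distance and matched greedily
one-to-one (ties broken by detection index, deterministic); unmatched
detections terminate or start trajectories. A minimum-total-distance
assignment (`method="optimal"`) is available and agrees with greedy on
well-separated data. No gap closing, no division handling, no
re-identification — identities are positional only.

## Displacement correlation

Displacements compare a cell's position at frame *t* with frame *t−1*
(consecutive frames only), with the axial component rescaled by the
voxel anisotropy. `r` is the cosine of the angle between the two
displacement vectors — exactly the parallel → +1 / antiparallel → −1
semantics — with a componentwise Pearson variant behind a flag for
sensitivity analysis. Pairs where either displacement magnitude is below
`eps_motion` (default 0.3 px/frame) have no defined direction and are
dropped; the number dropped is reported so the exclusion is always
visible, and the threshold should be varied when analyzing real data
with near-stationary cells.

"Neighboring" is not a unique notion; the default rule pairs cells
within 1.5× the frame's median nearest-neighbor distance (adaptive to
density), with Delaunay-edge and fixed-radius rules as alternatives. The
rule and its parameters are recorded with the output. For isotropic 3D
directions r is uniform on [−1, 1], so the coordinated fraction at
r > 0.8 has a closed-form baseline of 0.10 — a useful null against which
coherent motion is read. The time-resolved density plot normalizes each
time column to its own maximum by default (an overall-maximum mode is
available; the two read differently when pair counts drift over time).

## Junction morphometrics

PA detection: Otsu segmentation of the spot channel, size gate, then an
attachment test — the object's footprint dilated by 2 px must overlap
the Otsu-segmented actin mask. The attachment radius operationalizes a
visual criterion ("spots on actin bundles") and is configurable. Sizes
are maximum Feret diameters over the convex hull of *pixel corners*, so
a single pixel measures √2 rather than 0; this convention is validated
exactly against a brute-force all-corner-pairs oracle. For large
silhouettes (fusion axis length) the corner convention would add a
systematic half-pixel per side, so those use pixel centers instead.

TJ length: white top-hat (disk radius 4 px) suppresses broad structures,
Otsu thresholds the residue, a shape gate removes non-line components
(max Feret² / area < 8 — residual caps of round spots survive a top-hat
but fail this gate), and the segmentation is skeletonized to 1 px width.
Two lengths are reported: the raw skeleton pixel count (the classic
proxy; it undercounts oblique runs by up to √2) and a traced length that
decomposes the skeleton into branches between junction/end points and
sums polyline lengths through every 5th pixel, which removes the
digital-line bias (hexagonal test networks recover to <1%). Per-cell and
per-area normalizations are exact ratios of the pixel count. Cell number
comes from blob segmentation of the nuclei channel. Thresholds here are
free choices validated on synthetic tessellations only; they are not
claimed to reproduce any manual measurement.

Synthetic junction images render a Voronoi tessellation of seeded points
(or a regular hexagonal lattice) as the TJ channel (capsule-profile
segments, width ~2 px), the same borders thickened as actin, elongated
PA capsules of programmed length placed on border segments, and one
Gaussian nucleus per cell, plus additive noise. Ground truth stores the
exact clipped edge lengths, PA lengths and cell count.

## Fusion metrics

The synthetic doublet is the union of two discs; the programmed quantity
is the contact half-width `w(t)` (half the chord where the discs meet),
from which the center distance `d = √(r1²−w²) + √(r2²−w²)` and the
long-axis length `r1 + r2 + d` follow. For axis-aligned doublets the
generator shifts the configuration so the contact plane lies on a
pixel-center column: a binary mask cannot represent a point contact at
arbitrary subpixel phase (the columns adjacent to an r = 30 tangency are
~11 px tall), so snapping makes the programmed neck width exactly
representable. Neck widths beyond min(r1, r2) are clamped with a
warning.

Measurement: the long axis is the max Feret diameter after a 5 px
protrusion-removing opening. The contact length is the silhouette's
minimum cross-section width *perpendicular to the principal axis*,
searched between the centroids of the two lobes; widths are measured by
sampling the mask along exact perpendicular lines at 0.25 px axis steps
(bilinear interpolation), because any finite-width strip would pick up
the lobes' flanks near a narrow neck and overestimate it by O(√r). If no
interior waist exists the silhouette is convex — the pair has fully
coalesced — and the midpoint width is returned with a `fully_fused`
flag. Doublet length is reported normalized to the first measurable
frame; normalizing twice is the identity.

## Validation scope and problem sizes

Every pipeline is validated end to end against generator ground truth:
circularity curves to within 2%, phase boundaries to ±1 h, a programmed
+0.15 jump to ±1 frame; detection precision/recall and link identity
accuracy ≥ 0.95 on 30 nuclei × 100 frames at SNR 5; the
images-to-r pipeline to a mean absolute error ≤ 0.05 (estimated by
pooling three replicate movies, since a single movie's MAE fluctuates
around the information-limited expectation of ~0.045); hexagonal TJ
networks to within 5% (traced length); PA Feret lengths to ±1.5 px; and
fusion lengths to ±2 px with the programmed monotonicities. These sizes
were chosen so the full suite and the acceptance script each complete in
well under a minute on one CPU while keeping the binomial/σ confidence
intervals comfortably inside the asserted tolerances.

Known limitations: no Poisson noise or intensity heterogeneity; no track
gap closing; the fusion neck model is a two-disc union rather than a
curvature-driven neck; junction thresholds are synthetic-validated
defaults; and phase segmentation assumes a single latent→rising→static
progression (it will label oscillatory curves conservatively as rising).
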