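# Methods

This note documents the models and procedures `nemquant` implements, the
defaults that matter, the design choices made where the published
procedure leaves room, and what the synthetic-data tests do and do not
establish.

## Conventions

Stacks are 5-axis arrays ordered `(t, c, z, y, x)`, 0-based. Voxel size
`(dz, dy, dx)` in µm is mandatory metadata — raw pixel sizes differ per
microscope (0.18 µm, 0.25 µm, 0.063 µm …), so none is ever assumed.
Areas and lengths are computed in pixels and reported alongside µm
conversions. 2-D neighbourhoods are 8-connected and 3-D components
26-connected throughout (configurable).

## Nuclear segmentation and the ratiometric signal S

Preprocessing is percentile-clipped (0.5/99.5) min–max rescaling —
robust to hot pixels — a 1-px-radius 3-D Gaussian blur, and a per-slice
rolling-ball background subtraction (default radius 50 px). Rolling-ball
radii ≥ 16 px run on a 4× downsampled slice with the radius scaled
accordingly and the background upsampled before subtraction, the
standard large-radius speedup; the error is negligible because the
background varies on scales far above 4 px.

Segmentation is two-pass masked-object thresholding with a
marker-controlled watershed: a global Otsu threshold gives a coarse
foreground; within each coarse component a second, stricter Otsu
threshold yields the markers; the watershed of the inverted smoothed
intensity, constrained to the coarse mask, separates touching nuclei.
Each watershed object is then clipped back to its component's strict
threshold and re-filled (volumetrically, then per slice — a pure 3-D
fill leaks through sub-voxel gaps in the top/bottom cap of a closed
shell). This second pass is what places the label boundary on the bright
NE rim instead of at the generous global-threshold edge. Markers are
labelled on a 2-iteration dilated copy so that noise-fragmented pieces
of one shell share an id; marker geometry itself is unchanged.

The mid-slice is the plane with the largest segmented area (ties → lower
index). The membrane contour is a 3-px-wide band centred **one pixel
inside** the 2-D label boundary: automatic thresholds put the boundary
of a blurred bright shell at its outer tail, so a boundary-centred band
would sample roughly half cytoplasm and collapse S toward the
cytoplasm/nucleoplasm ratio. The background ("centre") contour — whose
geometry the published description leaves open — is a 3-px ring at 20%
of the equivalent radius around the 2-D centroid, well inside the
nucleoplasm for any convex nucleus. Then

&nbsp;&nbsp;S = median(sensor on membrane contour) / median(sensor on background ring),

and the alternative ratio S_alt divides the same rim median by the
NE-marker median over the whole mid-slice section, which is robust to
nucleoplasmic dimming. S is invariant under any positive global scaling
of the sensor channel; V = voxel count × voxel volume depends only on
the labels.

Tracking is greedy mutual-nearest-neighbour centroid linking with no gap
closing (broken tracks are discarded downstream, so closing gaps would
hide the defect being filtered). Links within `max_link_px` (130) are
made normally; a mutual-nearest pair farther apart but within 4× of it
is still linked with the displacement recorded, so a nucleus that jumps
is excluded by QC as one track with reason `jump_exceeded` rather than
surfacing as two anonymous broken fragments. QC applies the published
exclusions: mid-slice area < 8,000 px², border contact in any frame,
any displacement > 130 px, broken (non-movie-spanning) tracks, and
undefined background medians (marker leakage).

## Envelope fold counting

The mid-slice NE image receives only a light Gaussian blur (no rolling
ball — it would erase membrane detail) before a single-scale Sato
(Hessian tubeness) ridge filter at the filament thickness 1.6 (~3–4 px
structures). The response is thresholded with Otsu on its positive
support: lower thresholds (e.g. triangle) admit the wavy response halo,
whose skeleton grows hairs and phantom junctions. A consequence is that
the mask is the ridge *core*: on a clean 3-px ring it covers ~93% of the
ring pixels rather than all of them, a deliberate trade for exact
junction counting.

The mask is thinned to 1 px; open side branches shorter than 5 px are
pruned by iterative endpoint deletion (closed loops have no endpoints
and are untouched); 2×2 thinning clumps are resolved by deleting the
most-connected pixel, since a clump smears a junction over four pixels.
Branch points are skeleton pixels where ≥ 3 *distinct arms* meet,
computed as the crossing number (0→1 transitions around the cyclic
8-neighbourhood). A raw neighbour count misfires on the staircase
corners of any rasterized curve — a plain circle would score dozens of
"junctions" — whereas under the arm-count rule a simple loop scores 0.
The stricter published reading ("more than three neighbours") remains
selectable via the threshold parameter (4). Nearby branch points are
condensed by single-linkage clustering at a 4-px radius (connected
components of the radius graph) and the cluster count is the fold
metric; it is invariant under translation and under rotations by
multiples of 90°.

## ER morphometrics

Luminal markers (KDEL-type) are segmented by coarse threshold +
marker-controlled watershed with local-maximum seeding, touching
watershed fragments re-merged by connectivity. Membrane markers
(SEC61B-type) go through the per-slice ridge filter at thickness 1.6;
because tubeness vanishes at junctions and crossings although the
membrane is bright there, half of the raw intensity is blended into the
response before thresholding, so one network segments as one object.
Small gaps are closed per slice (disk 3) and only lumen-sized holes
(≤ 150 px²) are filled — membrane labelling outlines vesicles as rings
that should be measured as disks, while large pockets enclosed by
network loops must stay open or their stochastic sealing makes
object areas jump between frames.

Metrics are taken on the representative mid-section (z slice with the
largest total segmented area). Per 2-D object: area from the pixel
count, perimeter from the Crofton estimator (chain-length perimeters
bias Cir above 1 for small disks), Cir = 4π·A/P² clipped at 1.05 to
absorb rasterization excess (analytic shapes obey Cir ≤ 1, with equality
only for the circle). Objects under the small-vesicle cutoff (default
40 px², published range 30–50 px²) are dropped. Summaries are per FOV —
largest object area and unweighted mean circularity — because
neighbouring cells' ER cannot be attributed to single cells without a
plasma-membrane label. Time-lapse normalization divides by the frame-0
value (baseline ≡ 1; circularity then ranges 1–2 with > 1 meaning
rounder); single-time-point normalization divides by a control
condition's mean.

## GUV binding

A user line from the GUV centre to its edge defines a square crop of
side 2.4× the line length (the factor guarantees margin around the rim;
the crop geometry is not published). The membrane channel is blurred
(3-px 3-D Gaussian), segmented per slice (Otsu + hole fill), and the
slice with the largest GUV area is the middle section. The 3-px rim
contour is anchored to the membrane dye: a band around the segmentation
boundary restricted to pixels above half the band's membrane maximum.
A purely geometric band misses the rim when the boundary of the heavily
blurred shell sits a pixel or two off it — the membrane channel exists
precisely to localize the rim. Binding is the median protein intensity
along that contour divided by the reference signal (a 1 µM protein
solution in the source assay), making it invariant to joint rescaling.

Titrations are fit by bounded nonlinear least squares of

&nbsp;&nbsp;B(c) = B_max · c^H / (c^H + K′_d^H)

on per-GUV measurements, unweighted. Initialization: B_max⁰ = the
largest per-concentration mean, K′_d⁰ = the concentration at the
linearly interpolated half-maximum, H⁰ = 1. H is bounded to [0.5, 4] to
keep sparse titrations identifiable. 95% CIs are t-based from the
parameter covariance; degenerate data (all-zero binding) returns a
flagged non-converged fit instead of raising. At c = K′_d the model
gives B_max/2 for any H, and B(c) is strictly increasing and bounded by
B_max.

Two named generating presets reproduce the affinities reported for the
two sensor families: `alps-hypotonic` (B_max = 1, K′_d = 150 nM, H = 1)
with the 0 µM Ca²⁺ replicate design (n = 47, 14, 28, 57, 61, 87, 89, 74
at 0, 25, 50, 100, 200, 300, 400, 500 nM) and `c2-ca20` (K′_d = 20 nM)
with the 20 µM Ca²⁺ design (n = 41, 28, 39, 54, 73, 86, 73, 64). No
Hill coefficient is published for either sensor, so both presets use
H = 1 (plain Langmuir); B_max = 1 on the reference-normalized scale.

## FLIP

ROI 1 (5 µm diameter) sits at the bleach centre (2.5 µm bleach radius);
ROI 3 is the bleach centre reflected through the nearest nucleus
centroid (2c − p); ROI 2 — the "median axis" position, whose published
definition is ambiguous — is the midpoint between bleach centre and
centroid. The control ROI goes to the farthest other labelled cell and
is omitted with a warning if none exists. All ROIs are fixed across
frames. Traces are per-frame ROI means (median selectable; the published
plots do not name the statistic) plus the mean over an Otsu nuclear mask
of the frame-0 mid-plane, all normalized to frame 0. Summaries are the
pointwise mean with a t-based 95% CI across cells.

## Statistics

Group comparisons follow the published gate exactly, with the
Shapiro–Wilk/Levene gate level fixed at α = 0.05 (the publication states
α only for significance; 0.05 is assumed and configurable): both groups
normal → Levene → Student's t (equal variance) or Welch's t; otherwise
Mann–Whitney U; ≥ 3 groups: normal → Welch's ANOVA + Games–Howell,
otherwise Kruskal–Wallis + Dunn. Dunn's test is computed from the
rank-sum z formula with tie correction; p-values are unadjusted by
default (no correction is named in the source) with Bonferroni/Holm
selectable. Every result carries a gate trace (the Shapiro/Levene
p-values) sufficient to reproduce the routing, and stars at
0.05/0.01/0.001/0.0001. Two identical samples return p = 1 on the
Mann–Whitney path (a degenerate comparison carries no evidence).

Adsorption rates are pooled OLS of S on time across cells within the
linear window (t = 4–5 min). Breusch–Pagan (heteroscedasticity) and
Shapiro–Wilk (residual normality) run on the residuals; if either gives
p < 0.05 the model is re-estimated with HC3 robust standard errors. The
Durbin–Watson statistic is reported. With exactly two time points the
linearity/multicollinearity checks do not apply. `pearson_fit` returns
Pearson r, the two-tailed p and the OLS line with 95% CIs;
`area_to_radius` converts a polygon area to its equivalent circular
radius r = √(A/π).

## Synthetic scenes: what they emulate, and what they do not

Nuclei are ellipsoidal shells (default rim width 3 px, matching the
~3–4 px envelope scale implied by the filament thickness) whose sensor
channel has nucleoplasm intensity I₀ and rim intensity ρ·I₀, so the
rim-to-centre ratio is ρ by construction. Fold spurs are thick radial
ridges on the mid-plane shell, one skeleton junction each; their axes
are offset 0.1 rad from symmetric positions because an exactly diagonal
spur fuses smoothly into the rasterized rim outline and its junction
vanishes. Motion, volume and lysis follow per-frame schedules — the
osmotic time courses are data, not equations, so no biophysical swelling
model is imposed.

The ER scene is a connected backbone walk carrying 10 long branch
segments; vesiculation converts branches one-for-one into spheres from a
fixed, mutually clear layout (n = 20 vesicles at φ = 1), with the
backbone consumed only at φ = 1. Backbone, branch geometry, vesicle
layout and noise are drawn from separate seeded streams, so a φ sweep at
fixed seed is perfectly paired and the ground-truth direction of the
morphometrics is monotone by construction: every conversion step removes
low-circularity tube material and adds a circular object. Placement
margins (12 px between vesicles and from the tube) exceed the blur +
closing reach so that truth objects stay resolvable; without them,
neighbouring vesicles segment as low-circularity dumbbells.

Noise is signal-dependent shot noise — the Gaussian approximation of a
Poisson count at the photon budget (default 200 photons per unit
intensity), accurate in the confocal regime and chosen so that the
generator's random-number consumption is independent of the rendered
content, pairing noise fields across scenes that share a seed — plus
additive Gaussian read noise (σ = 0.01) and a planar background ramp
(amplitude 0.1) that exercises the rolling-ball correction. The
generators do **not** model a realistic PSF (blur is Gaussian),
photobleaching outside FLIP events, chromatic shifts, or cell-to-cell
biological variability; passing recovery tests therefore establishes
that the measurement chain is unbiased under controlled optics, not
that it is robust to every real-microscope artefact.

FLIP experiments are a two-pool recurrence: each bleach cycle zeroes the
bleach-site pool, and between cycles a fraction r of the measured pool
exchanges into it when the compartments are connected, giving
m_k = (1 − r)^k exactly; disconnected pools only jitter by read noise.

The four-nucleus QC scene places one nucleus under the size cutoff, one
touching the border, one jumping 150 px and one compliant, with
geometry chosen so every nucleus remains its own mutual nearest
neighbour across the jump — the jumper is then excluded as a single
track for the jump, not as two broken fragments.

## Problem sizes and numerical notes

Recovery suites use 96–256 px fields, 9–24 z planes and 20 seeds per
condition — small enough to run the whole suite in well under a minute
per stage while keeping every feature ≥ 10 px, where voxelization errors
stay below 3%. Mid-slice and mid-section ties break toward the lower
index. The circularity clip (1.05) and the Crofton estimator are
documented above; watershed label boundaries are refined as described
rather than tuned per scene. All generators are deterministic under a
fixed seed, and every randomized test derives its seeds explicitly.

## Known limitations

- The fold counter is validated on single-nucleus phantoms; heavily
  overlapping envelope outlines from adjacent nuclei in one mid-slice
  are not disambiguated.
- The lamina mask covers the ridge core (~93% of a clean 3-px ring),
  not the full ridge support; applications needing full-width masks
  should lower the threshold and accept noisier junction counts.
- ER metrics are per FOV by design; no single-cell attribution is
  attempted.
- The GUV pipeline assumes one vesicle per crop (the user line selects
  it); touching vesicles are not split.
- Isotherm CIs are asymptotic (t-based on the covariance); for small
  titrations profile-likelihood intervals would be more faithful.
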