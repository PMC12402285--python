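# Methods

## The behavioural model

A cell's apical area is modelled as
`A_c(t) = A_c(0) · (1 + a·sin(2πt/P + φ_c)) · g(t)` while it pulses,
where `a` is the pulsation amplitude (default 0.15, fraction of baseline
area), `P` the pulsation period (default 240 s), `φ_c` a per-cell uniform
phase, and `g(t)` a slow tissue-wide contraction (default 10% of area
linearly over the movie). A delaminating cell follows this until its
onset time, then stops pulsing and contracts monotonically so that its
area is `A_on · r(u)` with `u` the progress from onset (0) to completion
(1). The default ramp `r(u) = (1 + cos πu)/2` is a smooth monotone decay;
a linear ramp is available. Both are strictly decreasing, so programmed
events always satisfy the strict-area-decrease property the detector
relies on.

Onsets are drawn uniformly over the staged analysis window (default −30
to 100 min of dorsal closure; t = 0 is the staging anchor frame, standing
for the meeting of the posterior spiracles) and contraction durations
uniformly over 10–20 min. Planned events whose completion would land in
the last two frames are rejected and logged, since classification needs a
post-completion frame.

## Tissue geometry and kinematics

The tissue is a Voronoi tessellation of jittered-grid sites relaxed by
two Lloyd iterations, computed together with the sites' mirror images
across the field edges so that cells tile the rectangle exactly and
neighbouring cells share vertex indices. The movie advances this
shared-vertex mesh kinematically — there is no force balance. Each free
vertex sits at the average of the affine targets (isotropic area scaling
about the baseline centroid) of the cells containing it; vertices on the
field boundary are pinned. Because vertices are shared, the tessellation
tiles the plane at every frame by construction, and the averaging only
shrinks each cell's deviation from its programmed band, so pulsating
cells stay within their amplitude envelope.

Collapses are driven differently: at onset the cell's realized polygon is
frozen as an anchor, and its vertices follow a linear homotopy from that
shape to a programmed target configuration, rescaled every frame about
the homotopy centroid so that the exact polygon area equals
`r(u) · A_on`. This guarantees continuity at onset, strict area decrease,
and an exact final contact pattern:

- **rosette** — every vertex maps to the onset centroid, so all
  neighbours end on one multicellular vertex;
- **new junction** — two flanking neighbours are chosen as the
  non-adjacent pair with the longest shared edges; each of their shared
  edges maps onto the full residual segment (default 8 px, centred on
  the centroid, perpendicular to the line joining the two edges), and
  every other vertex maps to the nearer segment end. Exactly one finite
  bicellular contact survives; all other neighbours meet at the segment
  endpoints. Cells with no non-adjacent neighbour pair fall back to a
  rosette collapse (logged, and recorded in the ground truth).

Geometry classes are assigned by baseline cell shape — the most isotropic
chosen cells collapse as rosettes, the most anisotropic as new junctions —
matching the observation that new-junction delaminations occur in
anisotropic cells. Delaminating cells are drawn from interior,
pairwise-non-adjacent cells so events do not interact; this is a
simulation convenience, not a biological claim. After completion the
collapsed vertices freeze, so the new contact pattern persists.

## Rendering

Labels are rasterised per frame (uint16, background 0, persistent ids).
The junctional channel is a Gaussian ridge (σ = 1 px) along label
boundaries; the contractility channel adds medioapical Gaussian blobs
(σ = 4 px) at cell centroids to a half-amplitude junctional component;
the nuclear mosaic channel puts blobs only in marker-positive cells
(~10× background at the nucleus). Channel z-stacks follow a Gaussian
depth profile (σ = 1.5 planes) peaking at the designated apical plane,
with additive Gaussian noise (default σ = 2 intensity units) seeded per
(seed, channel, frame), so any subset of frames renders identically.
Fluorescence stacks are rendered only for requested frames (default: the
first five, which marker assignment consumes) to keep memory bounded.

## What the generator does and does not emulate

Emulated: pulsatile apical-area dynamics, the abrupt switch to unpulsed
contraction, rosette vs new-junction collapse topology, striped
(pair-rule-like) or Bernoulli marker expression with an optional
delamination hazard ratio for marker-positive cells, the two acquisition
geometries (2-min whole-tissue frames with 15 z-planes; a 30-s,
10-plane preset), depth-blurred two-channel rendering, and sensor noise.

Not emulated: mechanical force balance and neighbour deformation by
pulses, tissue curvature and projection distortion, photobleaching,
drift, segmentation errors (labels are perfect by construction; the
IoU relinker exists for imperfectly tracked real data), and apoptotic
signalling. Passing recovery tests here therefore shows the estimators
are correct on clean, geometrically faithful data; they do not measure
robustness to segmentation failure or optical artefacts.

## Onset estimation

The estimator fits an unweighted least-squares polynomial of degree 5 to
the raw area trace (the fit is the smoother; no pre-filtering) over a
window of `fit_window` frames (default 60) ending at completion,
evaluates its derivative at the window's frame times, and compares it
with the window-mean derivative m. Scanning backwards from the
penultimate window frame, the scan first descends until the derivative
sits below m — this skips the fitted polynomial's boundary wiggle at the
completion end, where a degree-5 fit can spuriously re-cross its mean —
and then reports the first frame whose derivative strictly exceeds m.
Exceedance requires a margin of `1e-9 · max(|m|, range(A)/window)`, so
an exactly linear trace (derivative constant and equal to its mean up to
float error) never triggers and instead uses the configured fallback
(window start, flagged). The estimator is invariant under affine
transforms of the area scale: shifting A(t) leaves the derivative
unchanged, and positive scaling scales derivative and mean together.

The 60-frame window covers a 10–20-min contraction plus a comparable
stretch of pre-onset pulsation at 30-s sampling; much longer windows
smear the fitted transition and bias the onset early, much shorter ones
leave too little pre-onset baseline.

## Detection and classification thresholds

A delamination is a track ending before the final frame with final area
< 25% of the track median and a 3-frame-median-smoothed area that is
non-increasing over the last 5 frames; border contact over those frames
flags the event `border_excluded` (kept in tables, excluded from
counts). Completion is the midpoint between the last present and first
absent frame. These thresholds replace manual event identification and
are configurable and logged.

Classification reads the first post-completion frame: among the
neighbours at onset, a newly adjacent pair with shared boundary
≥ 4 px (pixel adjacencies, counted directly or across a 1-px membrane
line, 4-connectivity) is a new junction; otherwise ≥ 4 neighbours with
pixels within 3 px of the collapse point is a rosette; anything else —
including completion on the movie's final frame — is ambiguous.

## Staging, counting, mosaic

Frames map linearly to minutes with t = 0 at the user-supplied anchor
frame. Windows are half-open `[lo, hi)` in minutes; events are timed by
completion by default (onset optional), and counts over a partition add
exactly. Two presets exist for the early/late comparison: the default
[−30, 30) and [30, 100), and a `fig3d` variant with [30, 90) as the late
window; neither is silently preferred. The mosaic ratio counts
marker-positive vs marker-negative delaminations inside the analysis
range; embryos with no marker-negative event have an undefined ratio and
are excluded from ratio-based tests (the per-embryo proportion
n⁺/(n⁺+n⁻) is provided as the alternative that needs no exclusion).

## Statistics

The rank-sum test enumerates all C(n₁+n₂, n₁) midrank assignments when
the pooled sample is ≤ 16 (two-sided p doubles the smaller tail, capped
at 1; all-tied data gives p = 1), and otherwise uses the normal
approximation with tie correction and a 0.5 continuity correction; the
16-sample limit keeps enumeration at ≤ 12,870 subsets. Group comparisons
of per-embryo summaries use an embryo-clustered permutation test
(difference of group means; p = (1 + #{|permuted| ≥ |observed|})/(n+1)),
with the embryo as the exchangeable unit. This replaces mixed-effects
count models: with per-embryo summaries and embryo-level permutation the
clustering is respected without distributional assumptions, though
equivalence with a negative-binomial mixed model is not claimed. No
multiplicity correction is applied by default; Benjamini–Hochberg is
available.

## Intensity protocol

Planes are ranked by summed reference-channel intensity, ties breaking
toward the most apical (lowest) index; the top 2 (configurable to 3) are
max-projected. The junctional mask is an Otsu threshold of that
projection (method and threshold always recorded; a constant image
raises an error directing to a fixed threshold) dilated with a disc of
radius 2 px. The measured channel is projected over the same planes and
its mean/median/integrated intensity reported inside the mask. Mask area
is non-decreasing in the dilation radius, and an additive offset to the
measured channel shifts the mean by exactly that offset. Intensities are
per-image; a per-cell variant intersects the mask with a cell footprint.

## Validation problem sizes

Validation uses 100-cell, 85-frame movies at 2-min sampling (seeds 1–5;
~50 programmed events) for detection and geometry; 50 traces at 30-s
sampling with 5% multiplicative noise for onset recovery; 100 replicate
two-cohort experiments (11 vs 5 embryos) for timing-effect power and 500
for type-I calibration; 200 simulated embryos per mosaic calibration;
and 10-frame two-cohort renders for intensity recovery. Cohort-level
calibrations draw per-embryo event tables directly from the behavioural
model rather than rendering movies — the rendered pipeline is validated
separately, and the table-level generators are what its ground truth
contains.

## Known limitations

- The onset estimator's error grows when the contraction occupies most
  of the fit window; with 2-min whole-tissue sampling a 10–20-min
  contraction spans only 5–10 frames, which bounds timing precision to a
  couple of frames.
- The new-junction residual length (8 px) and the classifier's 4-px
  junction threshold are linked; rescaling the imaging geometry requires
  rescaling both.
- The mean-intensity ratio between cohorts is diluted toward 1 by any
  additive offset shared by both (camera background); the planted-
  enrichment validation quantifies this at the default rendering
  brightness.
- Tracks are assumed pre-linked; the greedy IoU relinker is a
  convenience for well-behaved movies, not a tracking algorithm.
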