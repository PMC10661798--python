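# Methods

## Polarity measurements

A cell is a simple closed polygon (traced from a label image or given
directly); its centroid *C* is the area-weighted (shoelace) centroid and
its equivalent radius R_eq = √(area/π).  The basal-body patch centroid
*BC* is the unweighted mean of the cell's BB points — patches are point
annotations, so intensity weighting does not apply.  From these:

* **TD** = |*C* − *BC*| in pixels, and **TD_norm** = TD/R_eq.  Raw TD
  depends on magnification, so both columns are always emitted.
* **TA** = direction of *C* → *BC*.  TA is undefined when *C* = *BC*;
  it is reported as NaN, not an error, because a perfectly centered
  patch is a meaningful biological observation.
* **LD, FA**: LD is the maximum pairwise distance of the BB points,
  computed over convex-hull vertices (the hull maximizer equals the
  all-pairs maximizer); FA is the axial direction of a maximizing pair
  in [0°, 180°).  When several pairs tie at LD (relative tolerance
  1e-9), the smallest FA is reported so output is deterministic.  FA is
  computed per patch; a per-point-neighborhood reading of "Feret angle
  of each basal body" would need a neighborhood scale that point
  annotations do not define, so the patch-level quantity is the one
  implemented.

**Angle convention.**  All angles are measured counterclockwise from
the +x axis in a y-up frame.  Image coordinates put y downward, so
directions are computed as atan2(−Δy_image, Δx).  The same convention
covers TA, FA, rotational vectors and flow directions; degrees are the
external unit everywhere, radians are internal only.

**Rotational vectors.**  Each basal-foot point is paired with its
nearest basal-body point, one-to-one, greedy by ascending distance,
with ties broken by lower point index.  A distance gate (default 2× the
median foot-to-nearest-BB distance) prevents many feet from collapsing
onto one BB when a foot's true partner is missing; unmatched feet are
returned, not dropped silently.

**Summaries.**  Per group: n, mean ± SEM (SD/√n, ddof = 1) of TD and
TD_norm, circular mean and resultant length of TA (period 360°) and FA
(axial, period 180° via angle doubling), Rayleigh uniformity p for TA.
With two groups a two-tailed pooled t-test on TD is reported.  Cells
touching the image border have truncated polygons and are excluded from
summaries by default (overridable).

## Circular statistics

Axial data are handled by the standard doubling transform throughout.
The Rayleigh statistic is Z = nR² with the usual series-approximation
p-value (flagged below n = 5).  Watson's two-sample U² is computed from
the combined sort as U² = (nm/N²)[Σd² − (Σd)²/N] with d the difference
of empirical CDF fractions; subtracting the mean of d makes the
statistic invariant to joint rotation of both samples (the choice of
circular origin).  Tied values are resolved by evaluating both ECDFs at
the tied value, so every member of a tied block carries the same d —
this keeps the statistic independent of the arbitrary ordering of tied
observations, which matters for exchangeability under permutation.

The default p-value is a permutation test (999 relabelings of the
combined sample minimum; p = (1 + #{U²* ≥ U²})/(B + 1)), valid at any
sample size.  The asymptotic alternative evaluates the large-sample
null series 2Σ(−1)^{k−1}exp(−2k²π²U²) and reports the bracket implied
by the standard critical points (0.187 at α = 0.05, 0.268 at α = 0.01);
it is flagged when min(n, m) < 8.  Rose-plot binning uses half-open
bins; 24 bins by default (15°/7.5°), configurable.

## Synthetic epithelium

The generator is the validation harness: it produces data with exactly
the statistical structure the measurements assume, plus the ground
truth to score them against.

* **Tessellation.**  Poisson-disk seeds (dart throwing, spacing relaxed
  geometrically if the domain is too crowded) + one Lloyd relaxation
  step + Voronoi tessellation.  This yields convex, roughly isotropic
  cells with moderate size variation, resembling an ependymal mosaic.
  The label image is the nearest-seed rasterization (pixel centers at
  integer coordinates, matching scikit-image), so every pixel belongs
  to exactly one cell; point tables are authoritative and images are
  derived views, which bounds rasterization error separately from
  geometric error.
* **Angular model.**  Per-cell patch-offset direction ψ ~
  vonMises(µ, κ_trans); patch elongation axis ~ axial vonMises(µ,
  κ_feret) (doubled-angle construction); per-BB basal-foot direction ~
  vonMises(µ, κ_rot).  The von Mises family is the canonical circular
  analogue of Gaussian noise; κ = 0 gives the circular uniform and
  emulates disorganized (mutant-like) tissue, large κ the coordinated
  (wild-type-like) tissue.  Presets: wild-type κ = 8, offset 0.35;
  mutant κ = 0, offset 0.10.  The mutant offset and κ are calibration
  choices for a clearly disorganized regime, not measured values.
* **Patch geometry.**  The patch centroid sits at C + offset_frac·R_eq
  in direction ψ.  BBs are scattered in an ellipse (semi-axes 0.40/0.20
  R_eq along the elongation axis) with a blue-noise minimum spacing
  (default 3 px) and the scatter recentred onto the intended patch
  centroid, so measured patch centroids carry rasterization error only.
  Scatters that do not fit the cell are retried with geometric
  shrinking and finally clipped to the cell polygon, with the cell
  flagged.  Each BB's basal foot sits foot_offset_px (default 1.2 px)
  behind it; the BB spacing deliberately exceeds the foot offset
  because otherwise "nearest basal body" is ambiguous even in
  principle, as it is in real tissue where feet are short relative to
  BB spacing.
* **Defaults.**  200 cells on 512×512 px, 10 BBs per patch, µ = 40°
  — sized so that roughly 150 interior cells survive border exclusion,
  comparable to the ~200-cell groups a whole-mount analysis yields.

## Microsphere flow

Particles are Gaussian spots (σ = 1.5 px, uint16) advected each frame
by speed·û(θ(x)) plus an isotropic Gaussian step of scale diffusion_px.
The coherent regime uses a single global direction; the disorganized
regime uses a smooth vortex about the frame center, whose tangential
directions span the full circle — a minimal stand-in for turbulent
near-wall flow that still gives every particle a well-defined smooth
field.  Particles leaving the frame are dropped from later frames.
Initial positions keep a minimum spacing (default 10 px) and an 8σ
border margin so every spot is resolvable for several frames.  Defaults
(100 particles, 50 frames, 2 px/frame, diffusion 0.5 px) are
calibration choices for a clearly trackable video.

**Detection** band-passes each frame with a difference of Gaussians
(σ, 4σ), takes local maxima above a relative threshold, and refines
each to sub-pixel by fitting a parabola to the log intensity along each
axis — exact for Gaussian spots (~0.002 px here), with a center-of-mass
fallback at frame borders.  Peaks within 3σ of the border are not
reported because truncated spots localize with a systematic bias.

**Linking** is greedy gated nearest-neighbor: per frame, candidate
track–detection pairs within max_disp (default 3× the median
frame-to-frame nearest-neighbor step) are assigned in ascending
distance order, one-to-one; gaps up to max_gap frames can be bridged;
unassigned detections start new tracks.  At microsphere densities this
is equivalent to global assignment and easier to reason about.  A
track's direction is its net first→last displacement — robust to
per-frame jitter; the circular mean of per-step directions is exposed
as a secondary measure.  Tracks with net displacement < 2 px are
excluded from direction samples as Brownian-only.

## Cohort statistics

Allele frequency = variant alleles / (ploidy × individuals).  The 2×2
χ² with Yates correction uses χ² = N(|ad − bc| − N/2)² /
[(a+b)(c+d)(a+c)(b+d)], clamped to 0 when the correction overshoots
(standard practice; prevents spurious positives near independence), p
from χ²₁.  Population comparisons require the comparison cohort's
allele counts as explicit inputs; the package does not attempt to
reconstruct external database denominators.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume —
von Mises-distributed polarity angles around a shared direction,
patch offsets proportional to cell size, feet adjacent to their BBs,
spots moving under smooth flow plus diffusion.  It does not emulate
point-spread functions, camera noise, staining variability, manual
annotation error, 3-D tissue curvature, or cilia beat dynamics.
Passing tests therefore demonstrate that the measurement and testing
machinery is correct and well-calibrated on data satisfying its
assumptions, not that segmentation-free measurements could be taken
from raw micrographs.

## Numerical choices and problem sizes

Geometric oracle tests run brute-force enumeration (all-pairs Feret,
dense-grid centroids at 0.02 px spacing); invariance tolerances are
1e-6 degrees on angles and 1e-9 relative on exact coordinates, with
1 px allowed where rasterization intervenes.  Statistical calibration
uses 500–1000 simulated pairs with 999 permutations each (the
permutation statistic is vectorized over relabelings, so these runs
take seconds); parameter-recovery runs use 200-cell mosaics and
40–100-particle videos.  Single-seed reproducibility is guaranteed by
expanding one integer seed into independent per-component substreams,
so adding a component never perturbs another's draws.

## Known limitations

Watson U² p-value resolution is bounded by 1/(B+1) under permutation.
The greedy linker can fragment tracks when detections vanish near
borders; fragments still contribute (consistent) directions.  The
vortex field has a direction singularity at the frame center; particles
are never seeded exactly there.  Under the mutant preset the resultant
length of ~150 uniform angles has sampling spread of about 0.07, so an
occasional draw can approach 0.2.
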