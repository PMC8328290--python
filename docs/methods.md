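# Methods

This note documents the model, the numerical choices behind it, the
stimulus generators and the simulated observer, and what the tests do and
do not establish.

## Contours and curvature

A contour is an ordered point sequence, open or closed (closure implicit —
the first point is never duplicated).  Closed contours are canonically
oriented counterclockwise before processing, so signed curvature is
positive where the contour turns counterclockwise and a simple closed
contour has total turning +2π.

All processing happens on a uniform arclength resampling, which makes
index-based windows and arclength windows interchangeable.  Resampling
interpolates the coordinates with a cubic spline in arclength (periodic for
closed contours).  Linear interpolation was rejected: chord-wise
interpolation of a dense polygon leaves a low-frequency curvature ripple of
order 1% on a circle, which is far above the boundary detector's noise
floor; with spline resampling the ripple falls below 10⁻⁵ relative.

Curvature is estimated by lightly Gaussian-smoothing the coordinates
(kernel truncated at `smoothing_halfwidth` points, default 3, σ =
halfwidth/2) and applying central finite differences in the standard
formula k = (x′y″ − y′x″)/((x′)²+(y′)²)^{3/2}.  Closed contours wrap; for
open contours the first `halfwidth + 1` estimates copy the nearest clean
interior value — the kernel reaches `halfwidth` points past the end and the
difference stencil one more, so that is exactly the span contaminated by
edge padding.  Clamping one point fewer leaves a biased value that
contaminates every windowed mean within W of an end and produces spurious
boundaries on constant-curvature arcs.

Default sampling density is 512 points for closed shapes; open fragments
are sampled proportionally to their estimated visible fraction so that the
effective density matches the parent contour's.

The turning angle of an index range is Σ k·(C/n) over its points, i.e. each
point owns an equal share of the contour; partitions of ranges therefore
sum exactly to the whole-contour integral.  The **visible fraction** of an
open fragment is |turning angle|/2π.  This uses the *signed* sum (matching
the closure argument: a closed contour turns through exactly 2π), not
∫|k|ds, so fragments containing inflections under-estimate their parent
coverage; this is a known property, not corrected.

## The encoder

**Boundary rule.**  For each adjacent pair (a, b) the deviations of k(a)
and k(b) from their respective windowed means over ±W points are compared;
opposite signs mean a boundary.  Two numerical refinements:

* Deviations smaller than 10⁻⁴·max|k| carry no sign ("no opinion").  A
  strict sign product would seed boundaries from discretization ripple on
  exactly-constant-curvature contours; the deadband is two orders of
  magnitude above the observed ripple and two below the smallest genuine
  deviations seen on spline shapes.
* A boundary is declared wherever the deviation sign *flips between
  successive decided points*, placed at the first point of the new sign.
  This keeps a sign change detectable when the zero crossing lands exactly
  on a sample (where the pairwise product is zero, not negative) or inside
  a deadbanded run.

For open contours, windows truncate at the ends and points within W/2 of
either end carry no opinion — truncated means there are unreliable, and on
two-arc stimuli they otherwise produce spurious boundaries near the ends.

**Windows for fragments.**  W is a fraction of *whole-contour* length
(default 0.04, the rounding of the empirically equivalent 3.95%).  For an
open fragment the whole length is estimated as fragment length / visible
fraction; fragments with visible fraction below 0.05 are rejected as
uninformative.  An absolute window length (`window_arclength`) can override
the fraction, used when windows are specified in degrees of visual angle.

**Merging.**  Adjacent same-sign segments merge when their curvature ratio
is below T (default 1.18); the merged segment carries the
arclength-weighted mean curvature.  The merge *order* is not dictated by
the ratio rule alone, so the implementation merges the most similar
(smallest-ratio) pair first and recomputes after every merge; this is
deterministic and, on small chains, terminates in a state that exhaustive
enumeration of merge orders also reaches.  Greedy order does not guarantee
the globally minimal segment count on longer chains — no order rule does
without search — and the tests assert exactly the guaranteed property.
Three degenerate cases the ratio rule cannot decide:

* opposite-sign pairs never merge (an inflection always separates);
* two near-straight segments (|k| < ε, default ε = 10⁻⁴·2π/C) always merge;
* a straight/curved pair merges only if |k₂−k₁| < ε.

An absolute-difference merge mode (|k₂−k₁| < T) is retained as an option;
the ratio mode is the default and is what every experiment-facing default
uses, being scale invariant.

**Reconstruction.**  Segments are rendered as circular arcs chained from
the first segment's stored anchor, each starting with the previous arc's
end tangent — tangent continuity holds by construction.  For closed
representations the closure gap is reported; gaps below 2% of contour
length are distributed as a uniform affine correction along the rendering,
larger gaps are left visible.  Per-segment point counts scale with
arclength (minimum `points_per_segment`), so single-segment closed shapes
are not under-polygonized.

## Stimulus generators

* **Arcs and two-arc contours** are exact circular arcs sampled at ~1 px
  spacing, subject to the under-360° angular-extent constraint; the two-arc
  junction shares position and tangent, so tangent continuity is exact, and
  the junction index is returned as ground truth.  Arc lengths 120–250 px
  per segment and first-segment curvatures 0.0059–0.02 px⁻¹; the side with
  higher curvature is selectable.
* **Spline shapes**: 12 control points at fixed 30° spacing with radii
  uniform in [0.7, 1.3]·base radius (default 200 px), interpolated by a
  periodic cubic spline with chord-length parameterization, sampled at 1024
  points; self-intersecting draws are rejected and redrawn from the same
  seeded stream.  The radial-displacement distribution and the
  parameterization are package choices exposed in `SplineShapeSpec`.
* **Fragments** take a uniformly random consecutive 40% (by default) of a
  closed contour.
* **Deformed pairs** displace two adjacent control points; the second
  displacement magnitude is solved by 1D root finding so total contour
  length is preserved within 0.5%.  A band-targeted variant bisects the
  leading magnitude until the pair's physical similarity lands at a target
  drawn from a prescribed band — similarity is monotone in magnitude for
  fixed directions, so this converges quickly and keeps the candidate yield
  high.
* **Similarity** of two closed shapes is ½(|A∩B|/|A| + |A∩B|/|B|) by exact
  polygon intersection, with centroids superposed by default.  (The
  alternative reading "overlap over non-overlap" is not used; the displayed
  averaged-ratio form is.)

**Matched corpus.**  Candidate pairs inside the similarity band (default
[0.97, 0.98], bracketing a mean near 97.5%) are labeled with the
segment-count difference of their two encodings under the default
parameters and binned by that label (conditions 0–4).  Bins are then
subsampled to a common size so the bin means of similarity agree within
10⁻⁴ ("a hundredth of a percent"): every size-n subset of each (trimmed)
bin pool is enumerated, a common target mean is chosen to minimize the
worst bin's deviation, and each bin contributes its nearest-mean subset.
Exhaustive subset enumeration is exact and cheap at these sizes
(≤ C(24, 8) per bin); a shortfall in any bin raises an error carrying the
per-bin counts rather than silently relaxing the match.

## Analyses

* **Psychometric fitting**: 2AFC logistic (or cumulative normal) on a log
  stimulus axis, p(x) = γ + (1−γ−λ)·F(β(log x − α)), maximum likelihood
  with γ fixed (0.5) and λ fixed (0 by default).  The 75% threshold is read
  off the fitted curve.  Data indistinguishable from chance (likelihood
  flat against the guess-only model) raise an explicit unidentifiable-fit
  error instead of returning a meaningless threshold.
* **Breakpoint regression**: continuous hinge y = b₀ + b₁x + b₂·max(0, x−c)
  fit by least squares for every candidate breakpoint on a grid (the
  measured levels by default); highest R² wins, ties break toward the
  larger breakpoint (the more economical window).
* **d′** = Φ⁻¹(hit) − Φ⁻¹(fa), with perfect rates corrected by the 1/(2N)
  rule so the statistic stays finite.

## The simulated observer

The observer perceives stimuli only through their CC encodings.  Its noise
model — multiplicative curvature jitter on the remembered segments
(re-merged after jitter), an occasional spurious segment split, and
Gaussian noise on the decision variable — and its representation-distance
decision variable (segment-count difference plus the mean absolute
difference of the two turning-density step functions k(s)·C on a common
normalized arclength axis, weighted 1 : 0.2) are modeling additions of this
package; no empirical claim attaches to them.

* *Complexity task*: encodes a single-arc and a two-arc contour and calls
  the one with more segments more complex, guessing on ties.  With zero
  noise this is chance at ratio 1.03 (the encoder merges), near-perfect at
  1.9, and non-decreasing in between — the qualitative signature of the
  task.  The human 75% threshold (ratio 1.18) is an empirical constant
  consumed as the merge parameter T, not a simulation output; the package
  verifies instead that a synthetic 2AFC observer *constructed* with a
  known threshold is re-estimated correctly by the fitting code.
* *Fragment-matching task*: compares a noisy memory trace of a fragment's
  encoding against the encodings of the fragment and of its CC rendering at
  a probe window, choosing the closer.  Observer parameters: curvature
  jitter 0.10, decision noise 2.0.  This simulation is qualitative only.
  In particular it does **not** reproduce the human transition at a 1.29°
  window: re-encoding a constant-curvature rendering introduces
  segmentation differences even when the rendering is physically almost
  identical to the original, so the simulated discriminability is not
  monotone in window size.  The transition point is an empirical constant
  about visual memory precision; it enters the model only through
  W = 0.04·C, and the package verifies that the breakpoint regression
  recovers a known transition exactly.
* *Same/different task*: responds "different" when the representation
  distance between the noisy memory of the first shape and the encoding of
  the second exceeds a criterion (default 2.0, decision noise 1.0,
  curvature jitter 0.10 — set so that same-pair distances straddle the
  criterion while condition-4 pairs clear it).  Hit rates come from the
  matched corpus conditions; the false-alarm rate is shared across
  conditions from identical-shape trials.  Simulated d′ rises monotonically
  with segment-count difference even though physical similarity is matched
  across conditions — the model's core qualitative prediction.

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: 512-point
sampling; 50-shape reconstruction corpus (median overlap asserted ≥ 0.95;
typical medians 96–97%); 150 trials per ratio for the simulated complexity
task; 10⁴ trials per level for psychometric recovery (threshold within 2%);
matched corpora of 4–6 pairs per condition from pools of 2.5–3× that size;
300 different-trials per condition and 400 same-trials for the simulated
same/different task.  Monotonicity assertions allow a slack of 0.06–0.1 on
proportions/d′ for binomial noise at these trial counts.

## Known limitations

* The encoder operates on clean vector contours; no robustness to local
  texture (serrations, high-frequency modulation) is attempted, and no
  image-based contour extraction is provided.
* Spline shapes with near-self-intersecting necks can carry very high
  curvature; the 512-point default then leaves 1–3% error in the turning
  integral (the winding tests use 1024 points for this reason).
* The fragment-matching simulation is qualitative (see above).
* Greedy merging is order-optimal only on short chains; representations of
  pathological curvature profiles may depend on the merge order.
* The similarity-matched corpus generator's yield of high segment-count
  differences (conditions 3–4) inside a tight similarity band is a few
  percent of candidates; requesting large per-condition counts scales the
  run time accordingly.
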