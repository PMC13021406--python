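# Methods

## Problem and model

The package compares two lesion annotations of the same fundus image — a
*reference* set (detector output) and a *marked* set (learner input) — and
classifies every lesion as correct, falsely input, or missed. Four pathology
classes are modeled: microaneurysms, hemorrhages, soft exudates, hard
exudates. All computation happens on binary pixel sets in the image raster;
there is no sub-pixel geometry.

### From drawing to lesion

A drawn contour is an ordered list of 0-based `(row, col)` vertices.
Processing is: rasterize the polyline (closing the polygon when it has ≥ 3
vertices), dilate, morphologically close, fill holes, and extract connected
components. The assumptions behind each step:

* **Dilation + closing** (default: disk, radius 1) seal the ≤ 1-pixel gaps
  freehand strokes typically leave. Radius and element are configurable
  (`MorphologyConfig`); radius 0 disables both and only fills holes. The
  image is padded internally before the closing so the operation is exactly
  extensive (output ⊇ input) even at the border.
* **Hole filling** sets every background region not 4-connected to the grid
  border. Foreground uses 8-connectivity, background 4-connectivity — the
  standard duality that avoids topological paradoxes.
* Contours are accepted whether they are closed polygons or open strokes;
  the closing morphology is what seals small gaps. Overlapping contours of
  one pathology merge into a single lesion: on pixel-set semantics overlap
  is indistinguishable from a single region.
* Mask files (PNG/TIFF, nonzero = lesion) are componentized as-is, without
  the sealing morphology, so mask round-trips are bit-exact.

Lesions are ordered canonically — area descending, ties by `(min_row,
min_col)` of the bounding box — wherever a deterministic order is needed.

### Matching

Per pathology class, reference lesions are visited in canonical order. Each
computes IOU against every still-unassigned marked lesion and takes the
maximum; if it reaches the threshold (default **0.5, inclusive**) the pair is
recorded and the marked lesion leaves the pool. Two deliberate choices:

* **Conditional deletion.** A marked lesion is only consumed when the pair is
  actually recorded as correct. Unconditional deletion would let a weak,
  sub-threshold overlap consume a marked lesion that a later reference lesion
  matches well — contradicting the correctness criterion.
* **Deterministic tie-breaks.** Equal maximal IOUs resolve toward the lower
  canonical index. Together with the canonical visit order this makes results
  identical across runs and platforms.

Greedy matching is not globally optimal; a brute-force assignment oracle
(`optimal_match_oracle`, ≤ 7 lesions per side) exists for testing and the
suite checks greedy ≤ oracle everywhere, with equality whenever overlaps are
one-to-one. IOU is computed on the filled (post-morphology) pixel sets of
both sides, processed identically.

### Feedback

`percent_found = 100 · n_correct / n_reference`. The denominator is the
reference count (recall-style): the report answers "how many of the model's
lesions did the learner find"; false marks are separate counts. When the
reference has no lesion of a class there is nothing to find and the
percentage is 100 by convention — division by zero is avoided while false
marks stay visible. Percentages are stored at full precision; rounding is a
display concern. Reports serialize deterministically (no timestamps), so
identical inputs give byte-identical JSON.

### Severity grading

An ordered rule table with first-match semantics and default grade 0 maps
per-pathology lesion counts (plus an explicit proliferative flag) to grades
0–4. The shipped table: proliferative flag or ≥ 40 hemorrhages → 4;
≥ 20 hemorrhages, or soft exudates together with hemorrhages → 3; any
hemorrhage/exudate otherwise → 2; microaneurysms only → 1; nothing → 0.
Because every rule predicate is monotone in the counts and rules are ordered
by descending grade, the table is monotone: adding lesions never lowers the
grade (verified exhaustively over the count lattice in the tests). Grade 4
is not inferable from the four lesion classes alone, hence the explicit flag
and the extreme-count rule that keep all five grades reachable. The table is
a configurable stand-in for a severity classifier; the thresholds carry no
clinical claim, and lesion *locations* (the quadrant-based 4-2-1 rule) are
not modeled.

## Synthetic data

The generator emulates a detector and a learner, not retinal images: lesions
are random filled ellipses with class-typical semi-axis ranges
(microaneurysms 1–3 px, hemorrhages 3–8, soft exudates 4–10, hard exudates
2–6) on a 256×256 grid, with per-class counts drawn from small ranges (2–6,
1–4, 1–3, 1–5 respectively). Placement enforces a bounding-circle gap of at
least `min_separation` (default 2 · max radius + 2 = 22 px) between any two
lesions, so components never merge under the default morphology and any
marked lesion overlaps at most one reference lesion.

The learner model perturbs each reference lesion independently: keep exactly
(p = 0.35), shift by ≤ 25 % of the minor diameter (0.25), relocate far away
(0.2), or drop (0.2); two spurious lesions are added per case. The
quarter-diameter bound keeps IOU above 0.5 for convex shapes in the
continuum; because discretization can fray that bound for few-pixel lesions,
the achieved IOU is verified on the actual pixel sets and the shift shrinks
toward zero (an exact copy) until the certificate holds. Relocated and
spurious lesions are placed under the same separation constraint as
everything else, so their IOU with every reference lesion is exactly 0.
Outcome labels are therefore *certain*, never borderline, and the generator's
bookkeeping is an exact oracle for the whole pipeline — which the suite
confirms on 200 seeded cases.

What passing these tests does **not** show: performance on real fundus
images (no vessels, no optic disc, no intensity information, no correlated
lesion clusters), realistic learner behavior (no skill curves, no
systematically biased outlines), or clinical validity of the grading
thresholds.

## Numerical choices and degenerate inputs

* IOU of two empty pixel sets is undefined and rejected, not 0.
* The IOU threshold comparison is `>=` (the boundary value is correct).
* Sample SD uses the n−1 denominator; a singleton's SD is reported as 0 by
  convention for stable CSV output.
* SUS uses the standard Brooke keying (odd items positively keyed, even
  negatively); the score is separable and monotone per item, so its extremes
  (0 and 100) are attained analytically at the item-wise extreme responses.
* All randomness flows through `numpy.random.default_rng(seed)`; same spec
  and seed means identical cases, bit for bit.

## Problem sizes used in the checks

The verification suite runs at desk scale: morphology oracles on grids up to
50×50, matching oracles on ≤ 6–7 lesions per side (200 seeded instances),
pipeline recovery on 200 seeded synthetic cases, and exhaustive grading
enumeration up to 50 lesions per pathology (13.5 million count vectors,
vectorized). These sizes exercise every code path while keeping the whole
suite in seconds.

## Known limitations

* Greedy matching can differ from the optimal assignment when several
  lesions overlap each other heavily; the production path intentionally
  mirrors the tool's greedy procedure.
* One mask file per pathology on export: two lesions that touch pixel-wise
  would merge on re-read (the generator's separation guarantee prevents this
  for synthetic data).
* The grading table reads counts only — prominence by area or location is
  out of scope.
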