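# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `rhizograph`. Nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Input model and conventions

The pipeline expects flatbed scans of washed, spread roots: dark roots
on a light background, 600–800 dpi, grayscale TIFF or PNG. On load,
intensities are normalised to floats in [0, 1]; colour inputs are
reduced by luminance; polarity is normalised so that roots are the dark
class, using the background-majority heuristic (if the image median is
dark, the image is inverted once — idempotent by construction). All
coordinates are 0-based (row, col) with row 0 at the top. Physical units
come exclusively from the dpi (mm = px·25.4/dpi); a missing dpi is a
hard error rather than a silent default, because every downstream trait
would be silently wrong otherwise.

## Segmentation

Scanner backgrounds are not homogeneous — illumination gradients and a
moisture film produce smooth intensity trends comparable in magnitude to
the contrast of a 0.15 mm lateral. The segmentation therefore fits an
explicit background surface:

1. Edges are detected with a Canny-style detector whose hysteresis
   thresholds come from gradient-magnitude percentiles (90th/98th) with
   a floor relative to the strongest edge (5%/15% of the maximum). The
   floor matters on quantised or noise-free backgrounds, where the
   percentiles alone collapse onto the ambient ripple.
2. A 2nd-order bivariate polynomial (6 coefficients, coordinates scaled
   to [−1, 1] for conditioning) is fitted to pixels sampled away from
   edges by RANSAC: 200 iterations, minimal samples of 6 points, and a
   residual tolerance of 2× the robust spread (1.4826·MAD about the
   median residual) of a global pre-fit. MAD about the *median* rather
   than about zero is essential: with many dark outliers the pre-fit is
   biased and residuals about zero no longer reflect the inlier spread.
   The RANSAC seed is fixed by default so segmentation is deterministic.
3. Foreground detection then proceeds in two steps. Pixels darker than
   the surface by 3× the inlier residual spread are provably
   root-or-soil; because scans are blurred, this margin alone dilates
   roots by 1–2 px. An isodata-style iteration therefore re-estimates
   the foreground core intensity (median of the current foreground) and
   re-thresholds at the midpoint between core and background surface
   until the set stabilises, which places the boundary at the blur
   midpoint. No manual threshold is involved at any point.
4. Connected components smaller than 32·(dpi/600)² px are removed. At
   600 dpi this is a disk of ≈0.27 mm diameter — below any plausible
   root fragment at the ~0.34 mm lateral/primary scale, but large
   enough that free-floating soil specks (radius ≤ 2 px) do not enter
   the graph stage as fake root fragments. Specks *attached* to roots
   are deliberately kept; they are the noise the thinning stage is
   designed to absorb.

If an image appears polarity-inverted after normalisation the detector
simply finds no dark-side outliers and returns an empty mask; it never
silently swaps the classes.

## Thickness and the two-component mixture

The exact Euclidean distance transform (EDT) of the mask gives, at each
medial-axis pixel, the distance d to the nearest background pixel
centre; the local diameter is taken as 2d − 1. The −1 reflects the
pixel-centre convention: the centre row of a w-px ribbon lies (w+1)/2
from the nearest background centre, so 2d − 1 recovers w exactly. The
mask is padded before the EDT so foreground touching the image border
still sees background.

One diameter sample per skeleton pixel is pooled into a 1-px-bin
histogram H(χ) with N_m total medial points, and a two-component
Gaussian mixture

    P(χ) = W₁·N(χ|μ₁,σ₁) + W₂·N(χ|μ₂,σ₂)

is fitted by nonlinear least squares of the *bin-integrated* mixture
mass against H(χ)/N_m (trust-region solver, σ ≥ 0.25 px). Two
discretisation details matter at this bin width: (i) the mixture mass is
integrated over each bin rather than evaluated at the centre, since
lateral-component spreads are ~0.5 px; (ii) the histogram is padded with
three empty bins on each side so an overly broad component is penalised
for mass spilled outside the observed range. The stated objective is a
density match, not a sample likelihood; a sample-likelihood EM fit
(scikit-learn) is provided as `fit_mixture_em` and serves as an
independent cross-check in the tests, never as the implementation.

The least-squares problem is multimodal when the two peaks are very
unbalanced (e.g. a dominant 7-px primary mode next to a 3-px lateral
mode), so the solver is started from three deterministic
initialisations — a 1-D two-means split, a split at the valley between
the two strongest separated histogram modes, and a percentile split —
and the lowest-MSE solution is kept. Components are ordered by mean
(ties by descending weight): component 1 is the lateral class,
component 2 the primary class. Two derived constants drive the graph
stage: the score threshold θt = 2σ₁ (a config switch
`theta_from_variance` provides a 2σ₁² reading, which is dimensionally
inconsistent with a pixel threshold and off by default) and the calibre cutoff
(μ₁+μ₂)/2 separating lateral-like from primary-like thickness.

## Noise-robust thinning

The base skeleton is the topology-preserving boundary-peeling thinning
of scikit-image, which preserves the 8-connected component count and
yields a one-pixel skeleton. Its well-known weakness is boundary noise:
every attached soil particle spawns a short false branch, i.e. a false
root tip. The spur filter removes a terminal branch iff its chain-code
length is below 1.5·DT(junction) + 3 px: a spur caused by a boundary
speck can never exceed the local root radius plus the speck radius
(≤ 2 px in the modelled regime, +1 px margin), while genuine lateral
roots are an order of magnitude longer. Two guards keep the filter
honest:

* **No creeping.** When specks sit near a root's tip, the junction they
  induce makes the true terminal segment itself short; deleting it and
  iterating would consume the root bite by bite. At a junction whose
  other branches are also short and terminal, the longest candidate is
  therefore kept as the root's true continuation.
* **Topology.** Only branch pixels strictly between tip and junction are
  deleted, never the junction pixel, and components without junctions
  are never touched, so the component count is invariant. Deleting spurs
  can leave a 3-pixel clump of former junction-cluster pixels in which
  no pixel has degree 1; a re-thinning pass after each sweep restores a
  clean open end there.

Setting `prune_spurs=False` yields the plain noise-sensitive baseline,
used in tests to demonstrate the robustness delta.

## Graph construction

Skeleton pixels with one neighbour become end vertices; 8-connected
clusters of pixels with ≥3 neighbours become single junction vertices;
the pixel chains between them become edges carrying their ordered path,
chain-code length (Euclidean step norms: 1 axial, √2 diagonal), and
per-pixel diameter profile. Parallel edges, self-loops, isolated pixels
and vertex-free cycles (closed rings get one synthetic vertex and a
self-loop) are all representable, because the reduction rules need them.

Where two roots cross, the overlap blob skeletonises into two nearby
junctions joined by a bridge shorter than its own local diameter; such
junction pairs are merged into one vertex at build time (the bridge
pixels join the junction neighbourhood). Without this, the first
extracted root path consumes the bridge and disconnects the second.
Path pixel chains that jump such a merged junction are bridged by the
Euclidean step norm, so lengths are preserved to within the blob size.

## Scoring and reduction

Each edge receives the specific score αᵢ = (T̄ᵢ − θt)·lᵢ. Long thick
segments score strongly positive; thin segments score near zero or
negative. Reduction applies, iteratively to a fixed point:

* self-loop removal (root hairs and soil artefacts), plus hair-scale
  2-cycles (combined length below the local diameter), keeping the
  stronger member;
* **Rule 1**: negative-score edges at end vertices are laterals —
  removed;
* **Rule 3**: a terminal edge scoring lowest among its junction's ≥3
  edges is a (possibly positive-score) near-tip lateral — removed. Two
  guards: the rule requires a through-going (non-terminal) edge at the
  junction, and never removes a terminal edge that is both
  primary-calibre and longer than 120 px — at a crossing junction every
  edge is terminal and the weakest is a genuine root half, not a
  lateral;
* **Rule 2**: among parallel edges, keep the best; primary-calibre
  members outrank lateral-calibre ones before scores are compared
  (a long lateral detour can out-score a short thick connector purely
  through length);
* **Rule 4**: degree-2 vertices are contracted; the merged edge's T̄ and
  α are recomputed from the concatenated profile (α is not additive
  across unequal lengths);
* **overlap ribbons**: where roots cross at a shallow angle they run
  stacked for tens of pixels and skeletonise into one segment markedly
  thicker than the single-root legs meeting it (≥1.2× the thickest
  primary-calibre leg at its endpoints). Such a segment belongs to both
  roots at once and is contracted into a shared vertex. Comparing
  against local legs, not the global primary mean, keeps segments of a
  thicker-than-average root from being mistaken for ribbons;
* **Rule 5** (thickness-gated): at any ≥3-edge junction, the
  weakest-scoring lateral-calibre edge is pruned — this is what removes
  the thin "bridges" left where a lateral crosses a foreign primary. An
  *unconditional* Rule 5 (weakest edge regardless of calibre) exists as
  a fallback for graphs still above 80 vertices; it can break a primary
  root in two and logs when it fires.

Every surviving reduced edge records the ordered original edge ids it
covers, so accepted paths expand exactly onto the original graph.

## Primary identification

A primary root is a simple path between terminal vertices maximising
Σαᵢ. On graphs of ≤12 vertices the optimum is found by exhaustive
simple-path enumeration; larger graphs use best-first branch-and-bound
with the admissible bound "current score + all remaining positive edge
scores", which is exact (it only prunes provably dominated partial
paths). Extraction is greedy and edge-disjoint: accept the best
qualifying terminal pair, delete its edges, repeat. A path qualifies if
its score is positive, its mean thickness exceeds both θt and the
calibre cutoff, and its length is ≥120 px (5 mm at 600 dpi — soil-speck
fragments have positive scores too). After extraction, candidates
shorter than 25% of the plant's longest primary are demoted back to the
lateral class: the primaries of one plant are its long axes, and the
short stragglers are wide laterals or overlap residues. Vertex reuse is
allowed (crossing roots legitimately share junctions); edge reuse is
not. When two similar primaries cross, the greedy order can mis-pair
their halves (counts and totals are unaffected; the two per-root lengths
are).

## Lateral grouping and traits

On the original graph, non-primary edges form subtrees. Each subtree is
assigned to the primary whose path it attaches to; its tip count is the
number of end vertices it contains; subtrees touching several primaries
(overlap) are split edge-by-edge and tip-by-tip by shortest path
distance to the nearest attachment, and the split is logged. Components
touching no primary go to an explicit "unassigned" bucket (scan debris,
or laterals whose attachment was lost); their tips are included in the
plant-level lateral tip total but not credited to any primary.

Geometric traits use the local-cylinder model: a step of length δl at
diameter w contributes π·w·δl to surface area and π·w²·δl/4 to volume;
lengths are Euclidean step norms converted to mm. Diameter statistics
exclude samples within one local radius of junctions, where the distance
transform is inflated by the joining root. Per-primary linear lateral
density is reported both as tips/cm and as total lateral length per
primary length.

Length accounting closes exactly by construction: every original edge is
in exactly one of {some primary, some lateral group, unassigned}, so the
three totals partition the skeleton's total edge length.

## The synthetic scene generator

No public corpus of ground-truthed root scans exists at this pixel
regime, so the generator is the test bed. It emulates, per scene:
5 primary roots as smooth low-curvature curves (drift plus damped
sinusoids) at 9±0.5 px width (≈0.38 mm at 600 dpi); lateral roots at
1.5 tips/cm attached in the basal 8–85% of each primary's arc (the
apical elongation zone of a young cereal root is developmentally bare of
laterals), 4±0.4 px wide (floored at 3 px ≈ 0.13 mm, the resolvability
limit), ~130±35 px long, emerging at 40–80° and too gently curved to
bend back into the parent; a light background (0.85) with a linear
illumination gradient (≈0.05–0.08 across the frame); 150 soil specks of
radius 1–2 px, half attached to root boundaries (the hard case for tip
counting); Gaussian blur (σ=0.8) and sensor noise (σ=0.02) on the
intensity image only — the truth mask is rendered without anti-aliasing
and is exact. With probability 0.3 an adjacent pair of primaries swaps
bottom targets, forcing a crossing. Default canvas 2200×1700 px
(9.3×7.2 cm of tray).

Lateral tips are kept *visible*: a lateral whose distal tip would land
inside another root's footprint (or on a previously placed tip) is
retracted to clear ground, redrawn, or dropped. A tip buried under
another root leaves no image evidence at all — it is uncountable even
manually — so the generator's truth counts are by construction the
visible-tip counts that any scan-based method (or human annotator) is
measured against.

What the generator does not emulate: root hairs and their texture,
second-order laterals, diameter taper along a root, touching-but-
parallel root bundles, scanner vignetting beyond a polynomial trend,
and moisture halos. Passing the suite therefore demonstrates the
pipeline's logic under controlled realistic geometry and noise, not
performance on any particular scanner or species.

## Problem sizes and determinism

The acceptance analyses use 20 scenes at the default 2200×1700 px with
5 primaries and ~50 laterals each (~4 s per scene end to end); unit
tests use 900×700 px scenes with 3 primaries. Every random choice in
the generator flows from one seed; RANSAC uses a fixed seed; the
mixture fit and all graph stages are deterministic with explicit
tie-breaks (smallest edge id). Two runs on the same scene produce
byte-identical trait tables.

## Known limitations

* Crossing primaries of similar thickness can be mis-paired at the
  shared junction: counts, total lengths and lateral assignments are
  unaffected, but the two individual root lengths can be exchanged in
  part.
* Two primaries running near-parallel and repeatedly touching over
  hundreds of pixels form an extended mixed region that no local rule
  fully disentangles; in rare such scenes (about 1 in 100 generated
  ones) one of the pair is reported as two fragments.
* A lateral thicker than the calibre cutoff that attaches at a junction
  where every other edge is terminal can survive into the candidate
  stage; the relative-length filter demotes it unless it is also
  comparable in length to a primary.
* Roots thinner than ~3 px after segmentation merge into the lateral
  histogram peak and are not separable into higher-order classes; the
  mixture is fixed at K=2 by design.
* The unconditional Rule 5 fallback (graphs >80 vertices after
  reduction) can split a primary; it logs every removal so affected
  scans can be reviewed.
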