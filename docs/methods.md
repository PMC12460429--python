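# Methods

`citruspick` implements the geometric half of a robotic citrus-harvesting
perception stack: everything that happens *after* an instance-segmentation
network has produced fruit and stem masks. The package covers fruit-to-stem
association under an explicit distance constraint, picking-point localization
on the matched stem, the standard instance-segmentation evaluation metrics,
numpy reference implementations of three lightweight network building blocks,
and a synthetic scene generator that makes every stage testable against
analytic ground truth.

## Fruit-to-stem matching

Each stem region is summarized by a straight line fitted to its contour
points. Two fitters are provided:

- **Ordinary least squares** (`method="ols"`) minimizes vertical residuals and
  yields the slope/intercept pair (a_i, b_i) of y = a_i x + b_i. It is
  undefined for perfectly vertical point sets and raises with a pointer to TLS.
- **Total least squares** (`method="tls"`, the default) takes the principal
  axis of the centered point cloud (via SVD) and represents the line as an
  anchor point plus a unit direction. Stems hang near-vertically 30°–60° from
  plumb, which puts the slope form close to its singularity; the
  anchor/direction form has no such problem. The slope/intercept view is
  derived from it whenever the line is not exactly vertical, so both
  formulations coexist.

For a fruit region R with M pixels the centroid is the arithmetic mean of the
foreground pixel coordinates. The boundary is the inner contour (foreground
pixels 4-adjacent to background, an 8-connected curve), and the
centroid-to-boundary distances give r_min and r_max.

The distance from the centroid (x_c, y_c) to stem line i is the orthogonal
point-line distance d_i = |a_i x_c − y_c + b_i| / sqrt(a_i² + 1) (computed in
the anchor/direction form, which agrees with that formula and also handles
vertical lines). The nearest stem, l_min = argmin_i d_i, is the candidate;
the fruit is *matched* only when d_1 = min_i d_i is smaller than the fruit's
own radius d. The radius defaults to **r_max** — the fruit's full physical
extent, i.e. a stem line is accepted only if it passes through the disk the
fruit could occupy — with `radius_mode="min"` exposing the conservative
r_min variant. Ties in the argmin (within 1e-9 px) go to the lowest stem id.
Distances are measured to the infinite fitted line, not the stem segment.
One stem may be the best candidate for several fruits (two fruits on a shared
stem is a real topology and is generated as such); a fruit never matches more
than one stem.

## Picking-point localization

Given a matched stem mask: crop the bounding box padded by 2 px (offset
recorded for the inverse transform); binary opening with a 3×3
elliptical/cross structuring element to cut speckle and false bridges
(opening never adds pixels, so every later stage stays inside the original
mask); iterative thinning (`skimage.morphology.thin`) to a skeleton that
contains no full 2×2 foreground block; restrict to the largest 8-connected
skeleton component; take the longest geodesic path between skeleton endpoints
(degree-1 pixels) as the centerline, computed by Dijkstra on the 8-neighbor
pixel graph with axis steps weighted 1 and diagonal steps √2. The picking
point is the path pixel at half the cumulative arc length, translated back to
image coordinates. Ties on even-length paths resolve to the smaller path
index; single-pixel skeletons are their own pick point; closed loops (no
endpoints) fall back to a deterministic double-sweep diameter from the
lexicographically smallest pixel.

The cross-shaped default element rounds the four corner pixels of a perfect
square but leaves bars and stems intact; a full-square element is available
through the `kernel` argument wherever exact shape preservation matters.

## Evaluation metrics

Instance-level matching is greedy in descending prediction confidence (ties
by ascending instance id): a prediction is a TP when its best *mask* IoU
against an unconsumed same-class truth reaches the threshold (0.5 default);
each truth is consumed once; leftovers are FN. AP integrates the
precision-recall staircase using the all-point interpolation (monotone
precision envelope), mAP50 is the unweighted two-class mean, and
F1 = 2PR/(P+R). P, R and F1 are defined as 0 when their denominators vanish.
Because micro (pooled counts) and macro (mean of per-class rates)
aggregations genuinely differ — published tables in this area are often not
reconstructable from their own P and R to the printed F1 — the report carries
both. The picking-point detection rate is the fraction of ground-truth
points whose same-stem prediction lies within a pixel tolerance (5 px
default in the pipeline).

## Network building blocks

The three architecture components are provided as seed-deterministic numpy
forward passes with exact parameter ledgers — enough to verify every shape,
boundedness and parameter-economy contract without a training framework:

- **GhostConv**: a primary k×k convolution produces C_out/2 maps; a cheap d×d
  depthwise convolution of those maps produces the other half; concatenation
  gives C_out channels at unchanged resolution. With no bias the count is
  (C_out/2)(C_in k² + d²) against C_in·C_out·k² for the standard layer — a
  strict saving for C_in ≥ 2 (exactly break-even at C_in = 1, k = d). The
  cheap operation is fixed as depthwise with d = 3 and the primary/cheap
  ratio at 2, matching the canonical published form of the block.
- **CBAM**: channel attention from global average- and max-pooled channel
  descriptors passed through a *shared* two-layer MLP (reduction r = 16
  default), summed and sigmoid-squashed to M_C ∈ (0,1)^{C×1×1}; then spatial
  attention from a k_s×k_s convolution (k_s = 7 default) over the
  channel-wise mean/max planes, giving M_S ∈ (0,1)^{1×H×W}. The block applies
  F′ = M_C ⊗ F and F″ = M_S ⊗ F′, so |F″| ≤ |F| elementwise always holds.
- **Multi-scale heads**: lateral 1×1 projections of pyramid levels at strides
  4/8/16/32 fused top-down with nearest ×2 upsampling and a 3×3 smoothing
  convolution per branch. Passing four levels yields the extra stride-4 (P2)
  branch that gives small, slender stems a high-resolution output; passing
  three reproduces the baseline P3–P5 behaviour.

Where these blocks sit inside a particular backbone, and any training
concern, are out of scope: the components are exercised through forward-pass
contracts only.

## Synthetic scenes

The generator emulates the statistical and topological structure the
downstream stages assume, not orchard photometry:

- **Fruits** are axis-aligned ellipses with major radius drawn from
  (20, 36) px on a 640×640 canvas and axis ratio in [0.85, 1.0] — simple
  shapes keep the centroid/radius oracles analytic.
- **Stems** are constant-thickness (3–7 px) segments of length 40–80 px,
  inclined 30°–60° from vertical (the way citrus hangs), attached at the
  fruit boundary pointing radially away from the fruit center, and rendered
  only over the short segment near the junction — mirroring the annotation
  practice of labelling just the cut region. An optional single mid-bend of
  up to 15° exists (`stem_bend_max_deg`) but defaults to 0 so the axis
  midpoint oracle stays exact.
- **Topologies**: with probability 0.2 a stem serves two fruits placed
  flanking its axis (each centroid offset 0.35·r to one side, so d_1 < r_max
  holds for both); with probability 0.15 the scene carries an extra fruitless
  stem placed so its infinite line stays well outside every fruit's matching
  radius. Placement enforces separation margins that make the ground-truth
  association geometrically unambiguous — every fruit's own stem line passes
  (nearly) through its centroid while every other stem line stays beyond
  r_max. A whole-scene layout is retried up to 100 times before a
  `PlacementError` names the violated constraint.
- **Occlusion**: leaf-like random ellipses, each sized to remove roughly
  5–10% of an instance's area, are overlaid per instance until its visible
  fraction enters the configured band — mild keeps every instance above 60%
  visibility, moderate lands each in [30%, 60%], with 100 bounded retries.
  The truth records both the occluded and unoccluded rasters and the exact
  pixel-count visibility ratio.
- **Determinism**: scene i of a batch is generated from a child seed derived
  from (global seed, i) via `numpy.random.SeedSequence`, so any scene is
  reproducible in isolation and identical configs yield bit-identical
  rasters.

The 8:1:1 train/val/test split floors the ratio shares and hands remainders
to the largest fractional parts (ties to the earlier part); if a part would
be empty while there are at least three items, one item migrates from the
largest part — so 10 → (8,1,1), 4000 → (3200,400,400), 5 → (3,1,1).

### What passing on synthetic scenes does and does not show

The generator has no texture, lighting, perspective, canopy clutter, touching
fruit clusters, or segmentation noise; stem masks are exact and fruits are
near-circular. Success here demonstrates the *geometric* correctness of
matching and localization — the distance constraint, the argmin selection,
the skeleton midpoint, the metric arithmetic — under the intended topologies
and occlusion bands. It says nothing about segmentation quality on real
imagery, and real-world association accuracy will degrade with mask noise in
ways these scenes deliberately exclude.

## Problem sizes and numerical choices

The test suite and the reproduction script run hundreds of 640×640 scenes
with 1–6 fruits each (200 scenes for the matcher-vs-oracle check, 100 for
recovery and localization, 25 per occlusion level), and 500 random small
instance sets for the metric oracles — sizes chosen so every distributional
claim is exercised at scale while a full run stays interactive on one core.
Floating-point tie-breaks are explicit everywhere (argmin ties → lowest id;
path midpoint ties → smaller index; equal confidences → ascending instance
id), which is what makes the brute-force-oracle comparisons exact.

## Known limitations

- Matching uses the infinite fitted line; a long way from the fruit this can
  associate a fruit with a stem whose *segment* is distant. The synthetic
  separation margins avoid the case; real scenes may not.
- Under heavy occlusion the localizer returns the midpoint of the largest
  visible stem fragment, which is the correct behaviour for the method but
  differs from the unoccluded axis midpoint.
- The min/max radius choice genuinely matters for elongated fruits; both
  modes are exposed because published descriptions of the constraint are
  ambiguous between them, and `max` (the fruit's full extent) is the default.
- The evaluation considers mask IoU only; box IoU is not implemented.
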