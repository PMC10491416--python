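# Methods

This note records the models, parameters, and numerical choices behind
`vinebranch`, and the scope and limits of the synthetic scene generator
used to exercise them.

## Coordinate conventions

All geometry lives in raster coordinates: 0-based, x to the right, y
down, pixel centers at integer coordinates.  "Clockwise" means clockwise
as seen on screen, which in this frame is the positive shoelace
orientation.  Rasterization is even-odd with boundary pixels included: a
pixel belongs to a polygon when its center lies inside or on the
outline.

## Branch model

A *segmented branch* instance (a short quadrilateral piece of a branch)
is reduced to the minimum-area oriented bounding rectangle of its mask's
pixel centers (convex hull + rotating calipers, via shapely's
`minimum_rotated_rectangle`).  Corners are normalized to `w1..w4`
clockwise, `w1–w2` being the short edge whose midpoint is closest to the
image's upper left (ties on y broken by x, so a horizontal rectangle
takes its left edge as "top").  The rectangle yields the branch model
**B = (V, W)**:

- `V` — the long median axis: top short-edge midpoint, center, end
  short-edge midpoint.  As chains grow, `V` concatenates; the axis of an
  n-member chain has 3n points (plus one point per fork the chain runs
  through).
- `W` — the terminal corner pairs `(w1, w2)` and `(w3, w4)`, which
  anchor the search sector rays.

A *forked branch* instance is reduced to its rectangle's center point.

## Bidirectional sector search

At a chain's top terminal, the search sector has apex `v2` (the second
axis point), boundary rays toward `w1` and `w2`, central ray toward
`v1`, full opening `S = 2·arctan(short/long)`, and reach
`3 · |v1 − v3|` for segment candidates, `1.6 · |v1 − v3|` for forks.
The end terminal is symmetric (apex `v_{n−1}`, rays to `w3`/`w4`).
Membership is inclusive: offset angle `D ≤ S/2` and distance ≤ reach
(with a 1e-9 rad tolerance on the angle comparison so that exactly-
boundary points are kept regardless of rounding direction).

A segment candidate is tested at its *facing* terminal axis point and
must also pass the **reverse check**: the angle between the target's
central ray and the candidate's own facing axis direction must not
exceed `S/2`.  This is what prevents a chain from capturing a fragment
of a parallel neighbor.  The nearest qualifying candidate is merged
(ties broken by instance id); merging a fork closes that side.  Seeds
are processed largest rectangle first, and a consumed segment never
joins a second chain, so chains partition the segments.

## Secondary connection

The primary pass stops at every fork, so a branch running straight
through a bifurcation arrives split.  For each fork, the chains with the
fork at their tail ("main") and at their head ("secondary") are grouped;
each main merges the secondary with the largest interior angle at the
fork, provided it exceeds **100°** — straight continuations (≈180°)
join, side limbs (≈90°) stay separate.  This repeats to a fixpoint, so a
chain can run through several forks.

Chains separated by detection gaps (no shared fork) are joined by a
relaxed search: opening doubled (`D ≤ S`), reach `5 · dis`, applied from
both chains, plus a **deflection constraint** — each chain's terminal
axis direction must deviate from the joining line by at most its own
`S/2` — which rejects side-by-side parallel chains whose terminals see
each other.  Nearest qualifying pair first, to a fixpoint.

Finally, `prune_isolated` drops single-segment chains with no fork:
isolated fragments are overwhelmingly falsely detected leaves/petioles.

## Default parameters

| parameter | default | role |
| --- | --- | --- |
| `iou_dedup` | 0.15 | rectangle IoU above which the smaller duplicate is dropped |
| `depth_factor_segment` | 3.0 | sector reach for segment candidates, × local axis length |
| `depth_factor_fork` | 1.6 | sector reach for fork candidates |
| `free_depth_factor` | 5.0 | reach of the relaxed gap-joining search |
| `bifurcation_angle_deg` | 100.0 | interior angle above which chains join through a fork |
| `correct_branch_iou` | 0.9 | mask IoU above which a branch counts as correctly reconstructed |
| `match_iou` | 0.5 | IoU for detection precision/recall matching |
| `render_mode` | `"masks"` | chain mask = union of member instance masks (`"rects"`: rectangles) |
| `bridge_gaps` | true | add quads between consecutive members' facing edges |

All are surfaced in `Config` and the CLI (`--set key=value`).

## Chain rendering

A reconstructed chain is rendered to a mask for evaluation.  By default
(`render_mode="masks"`) the mask is the union of the member and fork
instances' own masks plus *bridge quads* — quadrilaterals spanning the
gap between consecutive members' facing rectangle edges — so the branch
is a connected region across detection gaps.  The alternative
(`render_mode="rects"`) uses the member rectangles instead of the
instance masks.  Mask rendering is the default because the
mask → rectangle → raster round trip is lossy for thin, nearly
axis-aligned fragments: the minimum-area rectangle of a staircase raster
a few pixels wide comes out axis-aligned and adds corner area, costing
up to ~12% IoU per segment, which needlessly penalizes a correctly
grouped branch under the strict IoU > 0.9 correctness rule.

## Evaluation

- Chains and ground-truth branches are matched greedily one-to-one by
  decreasing mask IoU; every ground-truth branch contributes (unmatched
  branches score IoU 0).
- **Acc_r** = 100 · (branches with IoU > 0.9) / (all branches).
- **mIoU** = mean branch IoU, percent.
- **Diameter**: length-weighted mean of member rectangle short sides
  (weights = long sides); **E_a** / **E_r** are the mean absolute (px)
  and mean relative (%) errors over matched branches.
- Detection **precision / recall / F1** use greedy one-to-one matching
  at IoU ≥ 0.5.

## Synthetic scene generator

The generator emulates the *output of* an instance-segmentation model on
a trellis scene, not the imagery itself.  Everything is a deterministic
function of `SceneSpec`, including its seed.

Scene layout (defaults): a 720×1280 canvas holds 5 branches in disjoint
vertical corridors, each a heading random walk growing downward —
per-step turn bounded by 0.18 rad, safely below the narrowest possible
sector half-angle arctan(1/4) ≈ 0.245 rad, and the heading confined to
±0.45 rad of the branch's initial heading.  Branch width is drawn from
U(9, 20) px and held constant; quads have raster aspect ratio in
U(2, 4) (shortened where the local curve bends), separated by gaps of
U(1, 3) px.  With probability 0.25 a branch carries a fork: a
near-square forked instance on its axis from which a lateral limb of 2–3
segments leaves at 0.55–0.95 rad; the fork instance belongs to the
ground-truth masks of both adjoining branches, and the lateral's axis
passes through the fork center.

Injected pathologies:

- **Dropout** removes each segmented instance independently with the
  given rate (fork instances are kept: in practice bifurcations are
  rarely the missed part, and removing them would make the scene's
  ground truth ambiguous).
- **Duplicates** add a shrunk (×0.9), shifted (±2 px) copy of a segment,
  rasterized from its transformed outline — overlapping its source above
  the 0.15 dedup threshold by construction.
- **Distractors** are low-aspect blobs standing in for leaves/petioles.
  Each placement is rejection-sampled against the pipeline's *own*
  linking predicates (primary sector capture in both directions and the
  relaxed free link, against every scene segment and every prior
  distractor), plus a 70 px center clearance, so distractors are
  isolated singletons by construction and `prune_isolated` must remove
  exactly them.

Ground truth per branch: the union of its member instance masks *before*
dropout (what a human annotator would label as the whole branch), the
true constant width as diameter, and the member id list.

### Generator limits

- Branches never cross or touch; occlusion is modeled only as dropout.
  Real trellis scenes contain crossing branches that the sector search
  must disambiguate purely by the reverse check; that regime is not
  generated.
- Width is constant per branch; real branches taper.
- The strict IoU > 0.9 correctness rule makes terminal dropout
  unrecoverable by design: with per-segment dropout rate p, both
  terminal fragments survive with probability (1−p)², and a branch
  missing a terminal fragment is capped at IoU ≤ (n−1)/n ≤ 7/8 for the
  generated 4–8 fragments per branch.  At p = 0.1 this bounds expected
  Acc_r near 81–85% no matter how well the surviving fragments are
  grouped — the reconstruction cannot honestly draw branch length no
  detector reported.  The mIoU and diameter metrics degrade gracefully
  instead.

## Numerical choices

- shapely ≥ 2.0 provides the convex hull, minimum rotated rectangle, and
  exact polygon intersection areas; `rect_iou` is therefore analytic,
  not rasterized.
- The COCO-style polygon rasterizer is an even-odd crossing-number scan
  over the polygon's bounding box with boundary-inclusion, matching
  shapely's `intersects_xy` on simple polygons (property-tested).
- Angle comparisons clamp cosines into [−1, 1] before `arccos`; sector
  membership adds a 1e-9 rad tolerance so boundary points are treated
  inclusively.
- Scene sizes, corridor layout and the turn bound are the package's own
  choices for making clean scenes unambiguous; they are not fitted to
  any dataset.
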