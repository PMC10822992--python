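# Methods

## Screening model

The pipeline reduces glaucoma screening to geometry on two axis-aligned
bounding boxes per image. Two independent single-output detectors — one
trained on optic-disc (OD) boxes, one on optic-cup (OC) boxes — localize
the structures; the diagnosis is then a deterministic function of the two
boxes. This mirrors the clinical logic (cup enlargement relative to the
disc) while avoiding segmentation: no ellipse fitting or mask-based CDR is
attempted, and the accuracy of the diagnosis is bounded by how well a
rectangle's extent tracks the structure's extent.

### Radius conventions

A box `(x_min, y_min, x_max, y_max)` with half-width `hw` and half-height
`hh` yields a radius under one of three conventions:

| convention   | formula            | reading                                  |
|--------------|--------------------|------------------------------------------|
| `euclidean`  | `sqrt(hw² + hh²)`  | center-to-corner distance (circumscribed) |
| `semi_major` | `max(hw, hh)`      | semi-major axis of the inscribed ellipse  |
| `vertical`   | `hh`               | clinical vertical CDR                     |

For every box `euclidean ≥ semi_major ≥ vertical`, with the last two equal
exactly when the box is at least as tall as wide. `semi_major` is the
default: it is the only convention under which the packaged reference
table's ground-truth radii reproduce exactly (all nine disc radii, e.g.
41.5 = half-height of a 73 × 83 box, and 22 = half-width where width
dominates), whereas the center-to-corner formula reproduces none of them
(55.27 vs the printed 41.5 for image 1). All three are implemented and
selectable so the discrepancy between the formula-as-stated and the
values-as-printed is visible rather than hidden.

### Decision rule

`CDR = r_OC / r_OD`, compared inclusively against a threshold of 0.6: the
packaged table classifies ratio-0.6 cases as glaucoma, so `≥` is the
default and a strict `>` mode is exposed. The threshold is applied to the
unrounded ratio; the one-decimal "display ratio" exists only for
reporting. A disc box with zero radius raises an error (an invalid disc
detection must not silently produce a diagnosis). Coordinates are
continuous pixels, origin top-left, `width = x_max − x_min` with no +1
pixel-count correction — again the convention under which the reference
radii reproduce.

### Reference-table fixture

The packaged nine-image table is stored verbatim and validated at load
time. Known internal inconsistencies are flagged, not repaired: the
ground-truth OC box column of rows 1–8 duplicates the OD column shifted by
one row; printed ground-truth ratios are derivable from printed boxes only
for images 1–2; printed predicted radii carry decimals derivable from the
printed integer predicted boxes only for image 2 (they appear to have been
computed from unrounded float predictions). Exact-reproduction tests are
restricted to the self-consistent entries; both classification columns are
fully consistent with the printed ratios under the inclusive rule and are
checked for all nine rows.

## Detector

A patch-sequence transformer regressing one box per image:

1. **Patches.** The preprocessed `S × S × 3` image is split into
   non-overlapping `p × p` patches, flattened row-major:
   `N = (S/p)²` tokens of `D = 3p²` elements. The reference configuration
   (S = 224, p = 32) gives 49 tokens of 3,072 elements; the partition is
   lossless and exactly invertible.
2. **Encoding.** Each token is linearly projected to `d` dimensions and a
   learned per-position embedding is added.
3. **Transformer blocks** (pre-normalization): `y = x + MHA(LN(x))`,
   `out = y + MLP(LN(y))`, where the MLP widths are `[2d, d]` with GELU.
   Multi-head attention uses `d/heads`-dimensional heads with the usual
   `1/sqrt(d_head)` scaling.
4. **Head.** The token matrix is flattened, passed through a
   dropout-regularized GELU MLP (reference widths
   `[2048, 1024, 512, 64, 32]`), and a final 4-unit layer with sigmoid
   emits corner fractions of the image side. At prediction time the
   fractions are rescaled to pixels and the min/max ordering of each
   coordinate pair is enforced by sorting.

**Loss.** Mean squared error between predicted and target corner
coordinates normalized to [0, 1] — the simplest regression loss consistent
with a 4-neuron output; no box-overlap (IoU-family) loss is used.

**Optimization.** Adam (β₁ = 0.9, β₂ = 0.999) with L2 weight decay 1e-4
added to the gradient, batch 16, initial learning rate 1e-3 decayed
linearly to 0 across epochs (a constant schedule is available).
Fine-tuning continues with momentum SGD (μ = 0.9) at batch 8; requesting
Adam there is honoured with a warning. Weights are Xavier-uniform from a
seeded generator; batch shuffling and dropout draw from the same run seed,
so identical seeds give bitwise-identical loss histories.

**Implementation.** Forward and backward passes are written directly in
NumPy (float64), with every layer's analytic gradient validated against
central finite differences in the test suite, and the attention layer
additionally against a brute-force softmax-attention computation.
Checkpoints are `.npz` archives with the architecture configuration
embedded as JSON; loading refuses a checkpoint whose configuration does
not match the expected one.

**Profiles.** The reference configuration (224 px, 4 layers, d = 64,
dropout 0.1/0.1/0.3) matches a thousand-epoch training regime and is the
default. The `desk` profile — 64 px images, 16 px patches (16 tokens of
768 elements), d = 32, 2 layers, head `[256, 64, 32]`, ≤ 50 epochs —
trains in seconds on one CPU. Dropout is disabled in the desk profile: at
50 epochs the limiting factor is optimization, not overfitting, and the
reference dropout rates leave the cup model underfitting the cup's *size*
(position is learned first), which destroys the ratio signal the diagnosis
depends on.

### Preprocessing

Images are resized to the model side (224 by default) on both axes —
aspect ratio is deliberately not preserved, since the side constraints
force a square — and normalized per channel as `(x − 0.5) / 0.5`, mapping
[0, 1] to [−1, 1]. Grayscale or empty inputs are rejected.

## Synthetic fundus generator

The generator emulates the features of a disc-centred fundus photograph
that the pipeline actually uses: a reddish background with a radial
vignette and Gaussian noise (clipped back to [0, 1]), a bright elliptical
disc, a brighter concentric cup whose semi-axes are the disc's scaled by
the sampled CDR, and dark quadratic vessel arcs radiating through the
disc. Ellipses rather than circles are drawn (axis ratio sampled from
[0.75, 1.0], elongation direction random) precisely so the three radius
conventions genuinely differ on synthetic data; an optional vertical cup
offset mimics vertical rim thinning so the `vertical` convention behaves
like the clinical vertical CDR.

Defaults: 224 px frames; disc semi-major axis uniform on 25–50 px (scaled
proportionally for other frame sizes), i.e. a disc filling roughly a
quarter to half of a disc-centred crop; true CDR uniform on [0.3, 0.9],
which straddles the 0.6 threshold symmetrically and yields balanced labels
(P(label = 1) = 0.5); 4 vessels; noise SD 0.02. All randomness flows
through one seeded generator; dataset writes (PNGs, annotation CSV,
manifest JSON) are byte-reproducible given (config, seed).

**Ground-truth boxes are analytic.** Each box is the exact continuous
tight bound of its ellipse, `(cx − a, cy − b, cx + a, cy + b)`, not the
bound of the rasterized mask; the rendered mask agrees to within half a
pixel. Consequently the semi-major box radius equals the ellipse
semi-major axis and the box-derived CDR equals the sampled CDR
identically — which is what makes the oracle property exact: replaying
ground-truth boxes through the geometry stage must give diagnostic
accuracy 1.0 and AUC 1.0, because the label is defined by thresholding the
same quantity.

**What passing tests do not show.** The generator has none of the hard
parts of real fundus photography: no peripapillary atrophy, illumination
artifacts, camera variation, myopic discs, or ambiguous cup margins, and
its cup is always brighter than its disc. Results on synthetic data bound
the pipeline's mechanics (the optimization works, the geometry is exact,
the metrics are correct), not its clinical performance.

## Evaluation

IoU, confusion counts, and the three rates are computed directly;
undefined denominators yield `None`, never a silent 0/0. ROC and
precision-recall curves are delegated to scikit-learn, whose conventions
match the definitions used here: thresholds at unique score values with
ties grouped, trapezoidal ROC area, step-function (non-interpolated)
average precision. The continuous CDR is the risk score — it is the
pipeline's only continuous output. The test suite cross-checks AUC against
an independent pairwise Mann–Whitney count (ties counted half) and IoU
against brute-force unit-cell counting on integer grids.

## Scaled-down learning experiment

The acceptance experiment trains both desk-profile detectors on 200
synthetic 64 px images (disc radius 10–18 px) for 50 epochs and evaluates
on 200 freshly generated held-out samples — held-out size chosen to keep
the prevalence-baseline comparison out of the noise floor. Typical
results: held-out mean IoU ≈ 0.63, end-to-end diagnostic accuracy ≈ 60–68%
against a ≈ 52–55% prevalence baseline, AUC ≈ 0.65–0.80, and exactly
accuracy 1.0 / AUC 1.0 when ground-truth boxes replace the detectors.
These numbers are produced by `scripts/acceptance.py` at run time, not
stored.

## Known limitations

- Diagnosis from axis-aligned boxes ignores disc tilt and non-elliptical
  cup shapes; the vertical convention is only a box proxy for the clinical
  vertical CDR.
- One model per structure means the cup detector cannot exploit the disc
  detection (no conditioning or shared trunk).
- The desk-scale detector's ratio precision (~±0.1) is far below what the
  0.6 rule needs for reliable individual-level screening; at that scale the
  experiment demonstrates learnability, not clinical utility.
- `rim_width` is a radius difference, not a measured rim profile; no rim
  thinning detection beyond the CDR is implemented.
- The NumPy implementation is CPU-bound and float64; it is sized for
  desk-scale experiments, not for training at 224 px over thousands of
  images.
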