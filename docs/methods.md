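# Methods

## Problem setting

Given two or more binary segmentation masks of the same head-CT slice series
(one per segmentation model) plus ground truth on a calibration set, the
package chooses and applies the set operation — pixel-wise union or
intersection — that best cancels the models' dominant error direction, then
evaluates the result per slice and in aggregate.

## Error profiling and strategy selection

For model *m*, `num_overseg(m)` is the sum over calibration slices of false
positive pixels and `num_miss(m)` the sum of false negatives. A model is
classified OVER if `num_overseg > num_miss`, UNDER if the reverse, NEUTRAL on
exact equality. The comparisons are strict: the selection rule is only
defined for the two strict cases, and equality is genuinely uninformative
about direction, so NEUTRAL models never force a choice.

Selection: if ≥ 2 models are OVER, intersect all OVER models; else if ≥ 2
are UNDER, union all UNDER models; otherwise (mixed or neutral with no
agreeing pair) the plan is intersection over *all* models. The default
direction reflects how encoder–decoder segmenters behave in practice — they
bleed outward more than they miss — and the plan's `rationale` string always
records each model's counts, its classification, and whether the
tie-unresolved default fired, so the decision is auditable downstream.

When more than two models agree in direction, all agreeing models are fused:
for intersection the n-ary and chained-pairwise forms are identical
(associativity), so nothing is lost relative to fusing pairs.

Profiling uses raw model predictions by default; `maskfuse profile
--filtered` profiles Gaussian-filtered predictions instead, since filtering
slightly shifts both counts and a user may want the profile to match the
variant they deploy.

## Metrics

- **IoU** = tp / (tp + fp + fn) on a slice; range [0, 1].
- **Hausdorff distance**: both masks are reduced to boundary sets (a
  foreground pixel is boundary iff any 4-neighbor is background, with
  off-image positions counting as background — so foreground touching the
  image border is boundary, and a mask bleeding off-image is penalized). The
  directed distance is the exact max–min Euclidean distance over all pairs
  (computed via an all-pairs squared-distance matrix, no percentile or
  rank approximation); the symmetric HD is the larger directed value.
  Distances are in pixel units: no physical spacing is attached to the grid.

Degenerate slices are defined explicitly because a whole-head series
contains all-background ground truth above the vertex:

- both masks empty → IoU = 1, HD = 0 (a correct all-background prediction is
  perfect);
- exactly one mask empty → IoU = 0 and HD is *undefined* (NaN sentinel).
  Undefined slices are excluded from `mean_hd` and counted in
  `n_undefined_hd`, rather than mapped to an arbitrary large constant that
  would distort means.

Series aggregation reports both the unweighted per-slice mean IoU and the
pooled IoU (IoU of confusion counts summed over slices, which weights large
mid-head slices more). Published per-series IoU tables rarely state which
aggregation they use, so both are emitted; comparisons in this package's
reports default to the per-slice mean.

## Post-processing

A sampled 2-D Gaussian kernel, default 9×9 with σ = 1, normalized to sum 1,
is convolved with the mask (treated as reals in {0, 1}) and the response is
binarized with a strictly-greater-than comparison at 0.5. Mechanism: an
isolated speck's maximal response is the kernel's center weight (≈ 0.162 for
the default kernel), far below 0.5, so it disappears; a pinhole's response
is one minus that, so it fills; interior pixels of large regions stay at
response ≈ 1. Borders use reflect padding so constant masks are exact fixed
points even at the image edge — zero padding would erode foreground that
touches the border, which skull-stripped slices legitimately do. The strict
comparison fixes the measure-zero tie at exactly 0.5 deterministically.

For fusion experiments the default order is filter-each-model-then-fuse;
`--order fuse_then_filter` applies the filter to the fused mask instead.
Both orders are exposed and labeled in the reports because either placement
is defensible and they differ only near boundaries.

## Synthetic benchmark

`generate_phantom_series` emulates the slice-wise structure of a whole-head
series: the default 31-slice, 128×128 phantom has per-slice brain area
following a unimodal profile `sin(π (i+1)/(n+1))` (small at the skull base,
maximal mid-head) with the top slice forced empty (above the vertex). Each
non-empty slice's brain is a perturbed ellipse — slight eccentricity, ±2 px
center jitter, and three low-frequency radial cosine modes with amplitude
σ = 0.04 — giving one dominant smooth component, which is the level of
realism the mask-level method actually consumes. `base_radius` defaults to
42 px so the mid-head brain fills a realistic fraction of the frame. The
lowest quartile of slices carries distractor blobs (probability 0.8 per
slice, 1–3 round structures, kept ≥ 3 px clear of the brain) standing in for
orbits and skull-base tissue.

`simulate_model_output` perturbs the ground truth per slice, in a fixed
order: boundary jitter (each pixel in the 1-px band around the contour flips
with probability `jitter`), then uniform dilation or erosion
(`dilate_px`/`erode_px`, mutually exclusive), then Poisson(`blob_rate`)
spurious blobs of radius `blob_radius` placed outside the true region —
preferring distractor structures with probability 0.7 — and clipped to stay
disjoint from it, then with probability `dropout_rate` one disk-shaped bite
out of the region. By construction a dilate-only model has exactly zero
misses and an erode-only model exactly zero false positives, which makes the
error-direction bookkeeping testable without tolerance.

The default three-model bundle (`paper_like_profiles`) mimics the qualitative
biases reported for the U-Net family: a moderate over-segmenter with
distractor-linked false alarms (dilate 1 px, blob rate 0.6, jitter 0.15,
dropout 0.10), a heavy over-segmenter bleeding at the skull base (dilate
2 px, blob rate 1.5, larger blobs), and a strong model with few small false
alarms (dilate 1 px, blob rate 0.2, jitter 0.10). All three therefore
over-segment, the selector chooses intersection over all three, and on the
default benchmark the fused series' mean IoU exceeds every single model's in
every one of 50 seeded runs (asserted at ≥ 90% to leave room for sampling
noise). The three model seeds are derived from one bundle seed
(`3·seed + k`) so the models' randomness is independent but reproducible;
the recorded default seed is 20210101.

What the phantoms do **not** model: CT intensities and noise (the method
consumes masks only), multi-component or folded cortical geometry,
inter-slice correlation of segmenter errors, and anatomically plausible
error shapes. Passing benchmarks therefore demonstrates the correctness and
the directional logic of the fusion machinery, not clinical performance on
real CT series.

## Numerical and I/O conventions

- PNG masks binarize at value > 127 (8-bit midpoint convention, deterministic
  for anti-aliased inputs); NIfTI voxels at > 0.5. Writing stores foreground
  as 255 (PNG) or 1 (NIfTI); write→read is the identity on valid masks.
- NIfTI orientation headers are ignored beyond axis order: volumes are split
  along the third axis ascending, index 0 = bottom of head. The method is
  orientation-agnostic, but mixed-source inputs must be consistently ordered
  by the caller.
- Coordinates are (row, col), 0-based, row 0 at the top; user-facing slice
  indices are 1-based with slice 1 at the skull base.
- Directory series order is lexicographic filename order; written bundles
  use zero-padded names (`slice_001.png`) so lexicographic equals numeric.
- All randomness flows through explicit integer seeds on the config objects;
  every generator is a pure function of its inputs, and CLI runs with the
  same config are byte-identical.

## Problem sizes

The shipped test suite and the acceptance script run the default benchmark
at 31 slices × 128×128 with 50 repetitions, and validate the metrics against
brute-force oracles on masks up to 16×16 (500 pairs) — sizes chosen so the
whole suite completes in well under a minute per concern on one CPU while
still exercising every code path at the benchmark's full per-series scale.

## Known limitations

- HD is exact but all-pairs; for boundary sets far larger than this
  package's slice sizes (thousands of points) a distance-transform
  formulation would be preferable.
- The tie-unresolved default (intersection over all models) is a fixed
  prior, not data-driven; callers with genuinely under-segmenting ensembles
  that profile as mixed should force `--operation union`.
- Pooled vs per-slice IoU can disagree noticeably when slice areas vary;
  reports include both, and downstream comparisons should state which they
  use.
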