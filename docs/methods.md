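# Methods

This note documents the models and procedures implemented in `cemcurate`,
the parameter choices that matter, what the synthetic fixtures do and do
not emulate, and the numerical conventions.

## Standardization

Sources are 2D images or 3D volumes of arbitrary scalar dtype with
optional voxel spacing (z, y, x) in nanometers.

**Intensity mapping.** Global per-source min–max to [0, 255] with floor
rounding: `out = floor(255 · (v − min)/(max − min))`, the maximum mapping
to 255. uint8 input passes through untouched; a constant image maps to all
zeros (the degenerate range has no information to preserve). Optional
percentile clipping (`clip_percentiles`, default off) robustifies against
hot pixels. Non-finite values are an error, not silently clipped.
Intensity inversion is off by default and applied per source flag, since
polarity metadata is rarely trustworthy.

**Size budget.** Volumes above `max_source_bytes` (default 5 × 10⁹) are
reduced by the smallest uniform integer stride f ∈ {1, 2, 3, …} applied to
all three axes that meets the budget. Stride subsampling (not
interpolation) was chosen because it is exact, order-preserving, and
introduces no new intensity values; the factor is recorded in the slice
plan.

**Anisotropy rule.** All three orthogonal planes are sliced when spacing
is known and `|z − mean(x, y)| / mean(x, y) < 0.20` (strict); otherwise
only xy. The symmetric relative deviation against the mean lateral spacing
makes the rule well defined when x and y differ slightly. Unknown spacing
is treated as anisotropic — slicing xz/yz planes of a distorted volume
would produce geometrically stretched, misleading sections.

**Tiling.** Coordinates are 0-based (row, col) with half-open crops
[y0, y0+224). Full grid windows come first; a remainder strip of width
r ∈ [112, 224) yields one edge-anchored full window at offset dim − 224
(flagged, overlapping the last grid window by 224 − r pixels — the overlap
is later subject to dedup); r < 112 is discarded. Whole images between 112
and 224 on an axis are reflect-padded to 224 (flagged `padded`); reflect
rather than zero padding avoids an artificial black border that would both
perturb the hash and look like a padding artifact to the filter. Images
below 112 on any axis emit nothing. This keeps every emitted patch exactly
224 × 224 uint8, so downstream stages never branch on size.

## Deduplication

**dHash.** The image is resized with area averaging (PIL `BOX` kernel) to
(hash_size+1) columns × hash_size rows; bit (r, c) = 1 iff
pixel(r, c) < pixel(r, c+1), strict, serialized row-major. With the
default hash size 8 this gives 64 bits. The construction is invariant to
global brightness offsets (adjacent differences are unchanged) and robust
to sub-pixel misalignment, which is exactly the redundancy mode of
consecutive sections. The resize kernel and bit convention are fixed so
hashes are portable across runs and machines.

**Grouping.** Within each source dataset, patches are linked whenever
their Hamming distance is strictly below the cutoff (default 12 of 64);
groups are the connected components of this graph (single-linkage, i.e.
transitive closure). Components rather than cliques were chosen because
cliques do not partition a set; single linkage matches the intuition that
a drifting stack forms one chain of near-duplicates. Comparison is
within-source only: across unrelated experiments an incidental hash
collision is not evidence of duplication. Exact pairwise comparison is
used (sources are at most ~10⁵ patches); the distance matrix is computed
by vectorized XOR popcount.

**Exemplars.** One member per group survives, drawn uniformly by a single
seeded generator over groups sorted by smallest member id, making the
result independent of traversal order.

## Informativeness filter

Four image-level statistics per patch:

| feature | default parameters | what it measures |
|---|---|---|
| `lbp_std` | LBP, 8 neighbors, radius 1, uniform method; border codes dropped | micro-texture diversity |
| `entropy_std` | 16-bin local entropy, 15 × 15 window (bits) | spatial spread of information density |
| `geomean_median` | geometric mean over 5 × 5 on intensities+1, shifted back | robust brightness level |
| `canny_mean` | Canny σ = 1 on the [0,1]-scaled image, hysteresis 0.1/0.2 | membrane/edge density |

The local entropy is computed from per-bin integral images over a square
window — a vectorized formulation chosen for single-CPU throughput; 16
bins at window 15 preserve the contrast between textured cytoplasm
(entropy std ≈ 0.5 bits) and flat resin (≈ 0.01). Canny thresholds act on
the [0, 1]-scaled image so they behave as fractions of the intensity
range: flat noise produces no edges, membrane steps do. LBP codes whose
neighborhood crosses the image border are excluded from the std so a
constant image scores exactly zero texture.

The classifier is a Random Forest (500 trees by default, fixed seed,
single-threaded for determinism); the informative probability is the
tree-vote fraction, and a patch is kept iff probability ≥ threshold
(default 0.5; ties keep, so the boundary is deterministic). The feature
configuration is frozen into the model at training time and enforced at
prediction time. A deep patch→probability classifier can be substituted
anywhere a model is accepted — the contract is just a callable surface —
but the Random Forest path is the implemented one.

**Ground-truth labeling** (for synthetic data): uninformative iff the
uniform-intensity area covers ≥ 80% of the patch, or the global intensity
std is below the contrast floor (default 10 gray levels), or the patch is
flagged as an artifact. AUROC is computed by the rank (Mann–Whitney)
formulation with midranks, so tied scores earn half credit.

## Encoder probes

The encoder contract is minimal: `pooled(image)` returns a fixed-length
activation vector, `feature_maps(image)` a (C, h, w) stack. Determinism is
assumed.

**Firing thresholds.** Per neuron, the 99th percentile of pooled responses
to `n_noise` (default 1,000) images with pixels iid uniform on [0, 255] —
the maximum-entropy distribution over the 8-bit range, used as the
"meaningless input" reference.

**Near-maximal sets and selectivity.** For a probe set of n images, a
neuron's Z is its top ⌈0.1 n⌉ responses (descending, index as final
tiebreak — equivalent to "above the 90th percentile" for distinct values
and well defined under ties). A neuron is selective iff its minimum
response over Z strictly exceeds its firing threshold; non-selective
neurons are excluded from the rate average.

**Distortions.** rotation(level° about center, reflect padding, bilinear);
blur(Gaussian σ = level); noise(additive Gaussian sd = level, seeded,
clipped); brightness(pixel × level, clipped); contrast((pixel − mean) ×
level + mean, clipped); scale(center zoom by factor, bilinear, anti-
aliased when shrinking, reflect-padded back). Identity levels are 0 for
the first three and 1 for the rest, and are returned bit-exactly (the
input is passed through), which makes the identity firing rate exactly 1
for any selective neuron. 90°-multiple rotations are exact pixel
permutations.

**Mean firing rate.** Per level and selective neuron: the fraction of Z
whose distorted versions still exceed the threshold; the curve is the
mean over selective neurons.

**Selectivity maps.** Each feature map is bilinearly resized to the image,
scored by Point-Biserial correlation against the binary truth mask
(identical to Pearson against the 0/1 mask; degenerate inputs raise
rather than return NaN; constant maps rank last). The mean of the top-k
(default 32) maps is min–max rescaled to [0, 1] and thresholded at 0.3;
agreement with truth is IoU (defined 1.0 when both masks are empty).

**Occlusion.** Windows of 61 px every 30 px (grid side
⌊(224 − 61)/30⌋ + 1 = 6) are zeroed one at a time; importance is the
similarity drop s_full − s_occluded of pooled-vector dot products against
the reference, min–max normalized over the grid, bilinearly upsampled for
overlay. The drop direction (rather than raw similarity) makes "this
region carried the match" read as high importance.

## Synthetic fixtures

The generators are pure functions of (config, seed); reruns are
byte-identical.

- **Informative patches**: smooth low-frequency background (bilinear
  upsampled coarse noise, mean 160 ± 25), 3–8 elliptical organelles with
  semi-axes 14–42 px, a dark ring membrane (width 3 px, intensity 20) and
  darker textured interior (mean 70), plus Gaussian speckle (sd 6).
  Intensities follow regular EM polarity. Uniform area is below 80% by
  construction.
- **Uninformative patches**: `resin` (near-constant bright frame),
  `padding` (zero frame with an informative corner block under 20% area),
  `low_contrast` (textured frame compressed below the contrast floor),
  `artifact` (flat frame with misregistered tile seams). Labels come from
  the same criteria the filter is tested against.
- **Volumes**: a base slice warped by a per-slice drift (default 0.5 px of
  smooth displacement plus unit speckle); drift 0 gives byte-identical
  slices. Adjacent slices hash within the dedup cutoff for small drift.
- **Corpora**: stacks of patch-sized slices with a configurable planted
  duplicate fraction (near-copies: ±0.3 px shift, sd 0.3 speckle — small
  enough that even near-flat frames stay within the Hamming cutoff of
  their original) and uninformative fraction, with per-patch truth.
- **Toy encoders**: `global_mean` (exactly permutation invariant),
  `corner_pixel` (maximally location-bound), `random_conv` (seeded 5 × 5
  kernel bank), `planted_filter` (random bank whose channel 0 is a
  smoothed dark-pixel detector, i.e. an organelle detector for the
  appearance model).

What passing tests on these fixtures shows: the pipeline mechanics —
tiling geometry, hash/grouping behavior, threshold rules, probe
arithmetic — are correct, and the filter separates classes that differ in
the four statistics. What they do not show: performance on real EM data,
whose texture statistics, duplication structure, and artifact modes are
richer than the appearance model; no claim of biological realism is made.

## Problem sizes and numerical choices

The default study runs a 5,000-patch synthetic corpus (ten stacks, 40%
planted duplicates, 30% uninformative, seed 42) end to end, and evaluates
the filter on labeled sets of 600 patches across five seeds (75/25
split) — sizes chosen so the whole study runs in minutes on one CPU while
keeping per-stage counts large enough for stable fractions. The
end-to-end filter model is trained on a 400-patch synthetic labeled set
when no model is supplied. One corpus seed fans out to per-stage seeds via
`SeedSequence([seed, stage_index])`, so stages are independently
reproducible; every stochastic operation takes an explicit seed.

Degenerate inputs are errors, not NaNs: single-class masks, constant maps,
empty probe sets, zero selective neurons, mixed-source hash sets, and
malformed manifests all raise with a diagnostic naming the offender.

## Known limitations

- The appearance model is deliberately simple; filter AUROC ≈ 1.0 on
  synthetic data says nothing quantitative about real-corpus AUROC.
- Exact pairwise hashing is O(n²) per source; beyond ~10⁵ patches per
  source an index (e.g. BK-tree) would be needed.
- MRC spacing follows the crystallographic Angstrom convention on read
  (converted to nm); NIfTI pixdim values are taken as nm as-is, which
  matches EM practice but not the NIfTI unit field.
- Video containers and remote chunked volumes are out of scope; 2D inputs
  are single images, not stacks of frames.
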