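# cemcurate

Curation of heterogeneous cellular electron-microscopy (EM) images into a
deduplicated, information-rich corpus of 224 × 224 8-bit patches — the kind
of corpus used to pre-train segmentation encoders — plus probes that
quantify what an encoder has learned.

Cellular EM data comes as 2D micrographs and 3D volumes in many formats,
bit depths, voxel spacings, and intensity polarities. Consecutive sections
of a high-resolution volume are nearly identical, and a large share of raw
crops show only empty resin, padding, or homogeneously stained interiors.
Training on such data wastes compute and biases learned features, so the
pipeline standardizes, deduplicates, and filters:

1. **Standardize** (`cemcurate.ingest`). Intensities are min–max mapped to
   uint8. Volumes larger than 5 GB are stride-subsampled to budget. A
   volume is sliced into xy, xz, and yz cross-sections when its z spacing
   deviates from the mean lateral spacing by less than 20%
   (|z − mean(x,y)| / mean(x,y) < 0.2), otherwise xy only. Each section is
   cut into non-overlapping 224 × 224 crops; a remainder strip of width
   r ≥ 112 yields an extra edge-anchored full window, strips with r < 112
   are discarded.
2. **Deduplicate** (`cemcurate.dedup`). Every patch gets a 64-bit
   difference hash (dHash, hash size 8): the image is area-averaged to
   9 × 8 and bit (r, c) = 1 iff pixel(r, c) < pixel(r, c+1). Patches of the
   same source dataset whose hashes fall within Hamming distance < 12 are
   linked into single-linkage groups; one random exemplar per group
   survives.
3. **Filter** (`cemcurate.info_filter`). Four image-level texture
   statistics — std of the local-binary-pattern map, std of the local
   entropy map, median of the local geometric mean, and the Canny
   edge-pixel fraction — feed a Random Forest. Patches with informative
   probability below 0.5 are culled. Ground truth follows the 80% rule: a
   patch is uninformative when ≥ 80% of its area is uniform-intensity, its
   contrast is below a floor, or it is dominated by an artifact.

The `cemcurate.probe` module quantifies encoder representations against a
minimal contract (`pooled(image)`, `feature_maps(image)`):

- **Invariance** — per-neuron firing thresholds are the 99th percentile of
  responses to 1,000 uniform-noise images; the mean firing rate is the
  fraction of a neuron's near-maximal images (top decile, Z) that still
  fire it after a distortion (rotation, blur, noise, brightness, contrast,
  scale), averaged over selective neurons.
- **Selectivity** — each feature map is resized to the image and scored by
  Point-Biserial correlation r_pb against a binary organelle mask; the
  mean of the 32 most correlated maps, thresholded at 0.3, gives a binary
  segmentation scored by IoU.
- **Occlusion** — 61 × 61 windows spaced every 30 px are zeroed one at a
  time; a window's importance is the drop in pooled-vector dot-product
  similarity to a reference view, min–max normalized over the 6 × 6 grid.

Everything is exercisable offline: `cemcurate.synth` generates seeded
EM-like fixtures (textured cytoplasm with dark-membraned elliptical
organelles, resin/padding/low-contrast/artifact frames, drifting volumes
with planted near-duplicates) with analytic ground truth, and toy encoders
with known invariances.

## Worked example

```bash
python examples/full_curation.py
```

builds ten anisotropic synthetic stacks (500 patch-sized slices, 40%
planted near-duplicates, 30% uninformative frames) and curates them:

```
raw:      500 patches
dedup:    298 patches (reduction 0.404)
filtered: 171 patches (retained 0.574)
```

Dedup removes at least the planted 40% duplication (flat resin frames are
mutual near-duplicates, so they collapse too), and the filter then drops
the surviving uninformative exemplars. `examples/` contains one script per
capability (standardization, dedup, filter training, encoder probes), each
printing the numbers it computes.

The same pipeline is available from the shell:

```bash
cemcurate synth --preset corpus --n 500 --seed 42 --out corpus/
cemcurate curate --input corpus/ --output curated/ --seed 42
cemcurate probe-occlusion --encoder random_conv --image patch.tiff --out occ/
```

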