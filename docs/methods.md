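# Methods

## The segmentation paradigm

Membrane-stained epithelia are classically segmented with the watershed
transform: the junctional staining forms ridges, flooding from regional
minima partitions the field into one basin per cell, and the basins are
separated by one-pixel watershed lines. Plain watershed is brittle on raw
micrographs (noise creates spurious minima; dim junction segments leak).
This package implements the deep-learning refinement of that idea: instead
of predicting a single boundary map, an encoder–decoder network is trained
to reproduce **seven** redundant views of a curated watershed
segmentation, and the seven predictions are fused back into a single
refined one-pixel mask.

### The seven-channel codec

Given a curated label image `L` (positive integer per cell, 0 on watershed
lines; the image frame always counts as boundary, closing cells at the
field edge), `encode_targets` produces, in fixed channel order:

| # | role        | construction                                             |
|---|-------------|----------------------------------------------------------|
| 0 | `mask`      | the one-pixel boundary mask of `L`                       |
| 1 | `mask_dil1` | channel 0 after one 3×3 binary dilation                  |
| 2 | `mask_dil2` | channel 0 after two 3×3 binary dilations                 |
| 3 | `neg_dil1`  | pixelwise `1 − mask_dil1`                                |
| 4 | `neg_dil2`  | pixelwise `1 − mask_dil2`                                |
| 5 | `seeds`     | one size-scaled interior seed region per cell            |
| 6 | `neg_seeds` | pixelwise `1 − seeds`                                    |

The dilated channels give the network thick, learnable targets; the
negatives act as an explicit background class; the seed channels provide
markers for seeded flooding at decode time.

**Seed construction.** The seed of a cell with area `A` has nominal radius
`r = max(1, floor(0.2·sqrt(A)))` (proportional to the cell diameter, with
the proportionality constant `c = 0.2` exposed in the API). Rather than
stamping a disk at an arbitrarily tie-broken centre, the seed is the set
`{p ∈ cell : EDT(p) ≥ max(d_max − r, 3)}`, where `EDT` is the euclidean
distance to the nearest non-cell pixel and `d_max` its maximum over the
cell. For convex cells this *is* the inscribed disk-like core of radius
≈ `r`; being a pure function of the distance transform it commutes exactly
with flips and right-angle rotations, which a coordinate tie-break cannot.
The floor of 3 px guarantees the seed never touches `mask_dil2` (euclidean
clearance ≥ 3 implies Chebyshev clearance ≥ 3 > 2). Cells too thin for
that clearance degrade to their farthest-interior plateau and are reported
in a warning list.

### Decoding and fusion

Each of the seven predicted probability planes is turned into a one-pixel
watershed mask, matched to the geometry of what the channel predicts:

* **channel 0** (thin boundary): flooding of the probability map itself,
  with two numerical safeguards — h-minima suppression of depth 0.02
  (spurious minima shallower than 2 % of the probability range do not seed
  basins; binary inputs, whose basins have depth 1, are unaffected) and a
  medial tie-break that lifts ridge plateaus by `10⁻³ ×` their interior
  distance transform so flooding meets on the plateau centre;
* **channels 1–4** (thick bands; negatives inverted first): binarized at
  0.5 and thinned to the band's medial line. A thick predicted band
  binarizes into a robustly closed curve even where the network is locally
  unsure, whereas direct flooding of these fat, noisy ridges oversegments
  (we measured per-channel AP dropping to 0.2–0.4 on trained-network
  outputs versus 0.95–1.0 for the band decoding, which is also exact on
  binary targets);
* **channels 5–6** (seeds; negative inverted first): binarized at 0.5 into
  markers, then seeded flooding of the mean boundary-oriented probability
  of channels 0–4; an empty marker set falls back to unseeded flooding and
  is logged.

The seven masks are averaged (equal weights by default) and thresholded at
0.5 — a strict majority vote. The vote is tolerant to one-pixel line
jitter: each mask supports every pixel within one pixel of its boundary
(3×3 dilation) before averaging, because seven independent watershed
decodings of the same tissue route equivalent lines with ±1 px
discretization differences, and a strictly pixelwise vote opens spurious
gaps exactly where the decoders disagree on which of two adjacent pixels
carries the line (we measured boundaries with 21 of 24 pixels above
majority whose three sub-majority pixels merged the two cells). The
candidate boundary set is then
*re-closed*: the 4-connected components of its complement seed a watershed
of the candidate's interior distance transform, so basins meet on the
candidate's medial line. This restores a valid one-pixel closed partition
whenever voting thickens or nicks a curve, is exact on already-thin closed
lines, and never invents a boundary where the vote removed one. Complement
fragments of ≤ 4 px (wedged junction pixels, vote noise) are absorbed into
the boundary — no epithelial cell is a few pixels large.

A single medial-line operator (`close_candidate_boundary`) implements this
re-closure everywhere; a subtlety worth recording is that it floods the
band's **interior** distance transform. Flooding a flat plateau instead
would leave the medial position at the mercy of queue order, which made
thick-band thinning non-deterministic in an earlier formulation.

### Connectivity and border conventions

Cells are 4-connected regions; boundary lines may run 8-connectedly (a
diagonal line still separates 4-connected regions). The image frame is
always treated as boundary, so cells touching the field edge are closed.
All label images are integer-valued with 0 reserved for boundary and
background; labels are assigned consecutively in raster order of each
region's first pixel.

## Network and training

The network is a LinkNet-style encoder–decoder: a VGG16-style encoder
(stages of 2, 2, 3, 3, 3 convolution–batchnorm–ReLU blocks at widths
64/128/256/512/512, 2×2 max-pooling between stages) mirrored by a decoder
(nearest-neighbour ×2 upsampling, one conv block per stage) with
*additive* skip connections from each encoder stage to the matching
decoder stage, and a final 1×1 convolution with a sigmoid head emitting
seven probability planes. Input tiles must be divisible by 32 (five
pooling stages).

The loss is the soft Jaccard (IoU) loss, computed per channel and averaged:
`J_c = (Σ y·ŷ + ε) / (Σ y + Σ ŷ − Σ y·ŷ + ε)`, `loss = 1 − mean_c J_c`,
with `ε = 1` smoothing empty-channel tiles (a flattened-tensor mode is
also provided). Training uses Adam with the two-phase schedule — learning
rate 10⁻³ for the first half of training and 10⁻⁴ for the second — for
300 epochs at batch size 24 on 256-px tiles in the full-scale profile.
Weights with the best epoch loss are kept. Encoder weights are randomly
initialized (He); nothing is downloaded.

Because no deep-learning framework is a dependency, the layers
(im2col-based convolutions, batch norm, pooling with deterministic
tie-breaks) carry explicit hand-derived backward passes, verified against
finite differences in the test suite. Everything runs on one CPU core.

A `tiny` preset (64-px tiles, 1/8 stage widths, batch 4) is the
test-suite workhorse; it trains in roughly two minutes of CPU time and is
the model used by all scaled-down end-to-end experiments.

## Tiled inference

Large images are reflect-padded (bottom/right; pads wider than the image
are applied in chunks) and covered by tiles of the network's input size
with stride `tile − overlap`. Only each tile's central crop is written to
the output, so every pixel is produced by exactly one tile and no blending
is needed. The default overlap is `min(32, tile/2 − 2)`; with small tiles
a proportionally larger overlap is needed because the network's receptive
field spans much of the tile.

## Synthetic epithelia

The generator supplies paired (membrane image, ground-truth label image)
samples with the statistical structure of the hard regimes in real
junctional imaging:

* geometry: Poisson-sampled cell centres, Lloyd-relaxed (3 iterations)
  Voronoi tessellation — epithelial monolayers are close to centroidal
  Voronoi tessellations. Default density 30 cells per 10⁴ px (mean cell
  area ≈ 330 px, comfortably above the seed-clearance scale);
* **codec-stable ground truth**: binary dilation is not injective on
  irregular one-pixel line jogs, so a raw pixelated Voronoi boundary is
  not always exactly recoverable from its dilated encodings. The generator
  therefore iterates encode → decode to its fixed point (2–4 iterations)
  and merges sliver cells whose interior clearance is below 3 px into a
  neighbour. The result differs from the raw tessellation by a few
  boundary pixels, and its exact partition is reproducible by the codec —
  which is what makes pixel-exact round-trip guarantees testable at all;
* staining: `continuous` mode draws solid boundary lines
  (boundary-to-cytoplasm intensity 0.85 : 0.25 by default); `dotted` mode
  emulates punctate adherens-junction staining by placing Gaussian beads
  (σ = 0.7 px) along each cell outline at 3-px arc-length spacing;
* a bimodal `giant_fraction` mode embeds a disk-shaped nest of tiny cells
  in a field of giant cells (area ratio 12 by default) using a
  multiplicatively weighted Voronoi partition; Lloyd relaxation is skipped
  in this mode because centroidal relaxation homogenizes cell areas and
  would erase the very contrast the mode emulates;
* imaging: Gaussian PSF (σ = 1 px), additive Gaussian noise (sd 0.04),
  optional Poisson shot noise, and a ±10 % linear illumination gradient.

All randomness flows from a single integer seed through one named
generator; datasets ship with a manifest from which every file regenerates
bit-identically.

What the generator does **not** emulate: curved-tissue projection
artifacts, anisotropic optics, cytoplasmic texture, debris, and the
long-tailed shape irregularity of real stressed tissues. Passing
end-to-end tests on these tissues demonstrates that the pipeline is
self-consistent and learnable, not how the full-scale network
performs on real micrographs.

## Scaled-down experiment sizes

The evaluation protocol bundled in `epiwatershed.experiments` uses
deliberately small problems so a full run takes minutes on one core: codec
round-trips on 20 random 96-px tissues; watershed recovery on 10 clean
96-px membranes; and an end-to-end run that trains the tiny preset on 32
synthetic 64-px tiles (120 epochs, two-phase schedule compressed to
60 + 60) and scores the full tiled-predict → fuse → label pipeline on 8
held-out 128-px tissues at IoU 0.7. Training uses per-sample flip and
intensity-jitter augmentation (rotation/zoom are disabled at this tile
scale because nearest-neighbour warping of one-pixel boundaries under
arbitrary angles aliases the thin-line targets). Under these conditions
the codec round-trip is exact (SEG = AP = 1.0), clean-membrane watershed
recovery is exact (AP = 1.0), and the end-to-end experiment reaches mean
AP ≈ 1.0 (≥ 0.9 across the seeds we ran), the residual errors being
single merged cell pairs on an occasional image.

## Known limitations

* The full-scale profile (256-px tiles, full VGG16 widths, 300 epochs,
  batch 24) is complete in configuration but is not trained by the test
  suite — CPU-only NumPy training at that scale is impractical; benchmark
  results on real microscopy data are out of scope here.
* The AP matcher is greedy by descending IoU; at thresholds ≥ 0.5 this is
  provably optimal (a cell can exceed 0.5 IoU with at most one partner),
  but below 0.5 it is an approximation.
* SEG follows the >50 %-overlap matching convention; ties at exactly half
  the cell area count as unmatched.
* The fusion stage assumes exactly seven channels with the fixed role
  order; alternative channel sets are out of scope.
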