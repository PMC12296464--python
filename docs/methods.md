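# Methods

## Model overview and assumptions

The picker assumes motion-corrected single-frame 2-D micrographs in which
particles are darker than background (the cryo-EM convention: higher
density, lower intensity), roughly disc-like at the scale of their known
diameter, and occupy a few percent of the image area.  It makes no use of
particle annotations; the only supervision-like input is one reference
micrograph with a binary particle mask, used solely to name which latent
cluster is "particle".

The stages and their contracts:

**Local background normalization.**  The per-pixel mean and standard
deviation under a centered circular mask of one particle diameter are
computed by FFT cross-correlation, which implies periodic boundary
conditions; the package keeps that convention exactly (the spatial-domain
test oracle wraps around the image edges).  Negative variances from FFT
round-off are clamped to zero, and the division is guarded by an epsilon
tied to the image's global standard deviation (1e-6 × global σ, floor
1e-12), so constant regions map to zero rather than NaN.  Normalization and
enhancement run at the native resolution, using the native-frame particle
diameter, before resizing: the statistics windows are defined by the
physical particle size, not by the working-frame raster.

**Enhancement.**  Wiener filter (5×5 window) → min-max rescale to [0, 1] →
CLAHE → guided filter of the Wiener image using the CLAHE image as guide
(radius = round(diameter/4), regularization 1e-2), output clipped to
[0, 1].  The CLAHE clip limit is configured in the familiar per-256-bin
convention (default 2.0) and divided by 256 for scikit-image's normalized
parameter; tiles are an 8×8 grid over the image.  The guided filter is the
standard box-filter formulation, implemented directly since no installed
library provides one.

**Masked autoencoder.**  Working images (default 1024×1024; every
micrograph is resized there regardless of aspect ratio) are cut into 64×64
tiles — 256 per micrograph, so five training micrographs supply 1,280
training images — and tiles into 8×8-pixel tokens (64 per tile).  Exactly
round(0.5 × 64) tokens per tile are masked, drawn uniformly without
replacement and independently per tile.  The encoder is a pre-LayerNorm ViT
of width 192 (depth 6, 3 heads, MLP ratio 4); the decoder is a width-96,
depth-2 ViT reconstructing pixel tokens.  The loss is the MSE over the
masked tokens' pixels only, the standard masked-autoencoder objective.
Optimization is AdamW (lr 1.5e-4, cosine decay, 5% warm-up, batch 64
tiles, weight decay 0.01 on matrices only) for 400 epochs by default; 20%
of tiles are held out and the checkpoint with the lowest held-out
reconstruction loss is kept — a label-free selection criterion, evaluated
with frozen masks so it is deterministic.

Two implementation choices matter for the downstream clustering:

* *Positional embeddings are learned, initialized trunc-normal 0.02* (the
  ViT/BERT convention) rather than fixed sine-cosine.  Fixed embeddings of
  O(1) amplitude dominate the latent geometry of a compact model, and
  k-means then segments by token position instead of content; small learned
  embeddings grow only as much positional information as reconstruction
  actually needs.
* *Model input is standardized per micrograph* (zero mean, unit variance
  over its tiles), putting content on a common O(1) scale across
  micrographs and making latents comparable when pooled.

The whole network is implemented in NumPy with explicit reverse-mode
gradients, in float64; gradients are verified against central finite
differences (relative error ≤ 1e-5 across all layer types), and runs are
bit-reproducible under fixed seeds.

**Latent clustering.**  Embeddings are taken per token (grid 128×128 at
defaults, stride 8 working pixels); per-tile pooling would be too coarse to
localize particles.  Train-set clustering is k-means, k = 4, k-means++
initialization, 10 restarts, tolerance 1e-6, fixed seed, on latents pooled
from all training micrographs (capped at 200,000 vectors by seeded uniform
subsampling), with no feature scaling — the encoder output is itself the
clustering space.  Cluster centers are sorted lexicographically after
fitting so cluster indices, and therefore tie-breaks, are reproducible.
The reference mask is reduced to the embedding grid by a ≥50%
pixel-coverage rule; the particle cluster is the one maximizing the
precision-style ratio |cells in cluster ∩ particle cells| / |cells in
cluster| (ties: larger intersection, then lower sorted index).

Micrograph-specific refinement assigns each grid cell to the nearest of
the four train-set centers (lower index on ties), seeds the particle set
with the particle cluster's cells, then for k = 3, 4, 5 re-clusters that
micrograph's own latents and keeps the cluster with the greatest overlap
with the previous particle set.  **Overlap is scored as the enrichment
fraction |C ∩ prev| / |C|**, not the raw intersection count: when the
previous set is only partially enriched in particle cells (typical for the
k = 4 train-set cluster, where background cells outnumber particle cells),
the raw count systematically follows the largest background cluster, and on
the synthetic benchmark this loses the particle cluster entirely in 3 of 5
micrographs; the enrichment score recovers it in all of them.  Ties break
toward the larger intersection, then the lower sorted index.  An empty
initial particle set yields an empty mask with a logged warning rather than
an exception, so batch runs continue.  `max_iters` is interpreted as the
final cluster count (default 5 → rounds at k = 3, 4, 5).

**Post-processing.**  The binary grid mask is smoothed with a uniform 3×3
mean filter (zero padding), bilinearly upsampled to the working frame with
edge-clamped boundaries (reflection would manufacture phantom extrema at
borders), and thresholded: 101 evenly spaced thresholds in [0, 1] are
evaluated and the one whose foreground fraction is closest to the target —
4% of the image, the typical particle-area statistic — is chosen, ties
going to the stricter threshold.  8-connected components become candidates
(centroid, equivalent radius √(area/π), score = mean map value), filtered
in order: radius > 1.5 × particle radius dropped; centers closer than half
a diameter to an edge dropped (partial particles); greedy non-maximum
suppression in descending score with a one-diameter exclusion radius.
Centers are finally divided by the per-axis resize scales to return to
original-micrograph pixels.

**Metrics.**  Box IoU of axis-aligned squares of side one particle
diameter; greedy one-to-one matching in descending IoU (deterministic
tie-breaks by index); true positive iff IoU ≥ 0.6 (the threshold is
configurable); precision defined as 0 when there are no predictions;
per-micrograph metrics averaged unweighted across the test set.  On
instances with well-separated annotations the greedy matching provably
attains the optimal matching cardinality, and the tests verify equality
against an exhaustive oracle on small instances.

## Coordinate and file conventions

Coordinates are 0-based, origin top-left, x = column, y = row, everywhere.
STAR files are written with `rlnCoordinateX`/`rlnCoordinateY` in
original-micrograph pixels (RELION/cryoSPARC interoperability); `.box`
files store top-left corners with the box side equal to one particle
diameter, and centers are recovered by adding half the box size.  MRC
images are MRC2014, modes 0/1/2/6, single section; stacks are rejected.
Round trips are lossless to ≤ 1e-3 px.

## Synthetic data: what it does and does not emulate

The generator draws uniformly placed non-overlapping discs (minimum
separation 1.5 diameters, at least half a diameter from borders), softens
their edges with a Gaussian of σ = diameter/8, and subtracts them at a
stated depth (default 3.5 noise-σ) from a background of i.i.d. Gaussian
noise plus a linear illumination ramp of one noise-σ peak-to-peak along a
random direction — a stand-in for ice-thickness gradients.  The defaults
(256×256 images, six 24-px particles ≈ 4% area) define the package's
benchmark conditions and sit at the operating point the post-processing
assumes.

Deliberately absent: CTF ringing, structured ice contamination, particle
shape/orientation variability, and contrast heterogeneity between
particles.  Passing the benchmark therefore demonstrates that the
machinery — normalization, representation learning, cluster tracking,
thresholding, matching — is implemented correctly and is reproducible; it
does not establish picking quality on real micrographs, where contrast is
weaker and heterogeneous.

One consequence is worth spelling out: on real data, deepening the
hierarchical refinement (larger final cluster count) raises precision while
*lowering* recall, because weak particles drop out of tighter clusters.  On
the homogeneous synthetic particles no such dropout occurs — every particle
survives tightening — so deeper refinement raises precision *and* recall
(the looser k = 3 masks instead lose detections by merging neighbouring
particles into oversized components that the radius filter removes).  The
precision direction reproduces; the recall direction is a property of
heterogeneous real data that this generator intentionally does not emulate.

## Scaled-down (desk) profile

`RunConfig.desk()` switches to a 256-px working frame, 32-px tiles (64 per
micrograph, 16 tokens per tile), a depth-2 encoder / depth-1 decoder and 30
epochs — sized so that training on five micrographs plus picking and
evaluating five held-out ones completes in a few minutes on a single CPU
core, which is also the profile the test suite uses.  The latent width
stays at 192 so clustering behaves identically to the full-scale profile.

## Numerical choices and degenerate inputs

* k-means everywhere: scikit-learn's Lloyd algorithm, k-means++, 10
  restarts, tolerance 1e-6, seeded; verified against a plain Lloyd oracle.
* All tie-breaks (nearest-center assignment, cluster selection, threshold
  selection, NMS ordering) are documented above and deterministic.
* Constant images normalize to zero; all-zero prediction maps return the
  strictest threshold with a warning; empty particle sets round-trip
  through every writer.
* Per-micrograph seeds in dataset generation derive from a
  `SeedSequence`, so datasets are reproducible and micrographs distinct.

## Known limitations

* The MAE is CPU-bound NumPy: full-scale training (400 epochs, 1024×1024
  working frames) is practical overnight but not interactive; the desk
  profile exists for exactly that reason.
* A reference mask is still required to *name* the particle cluster; the
  method is annotation-free in the sense that no per-particle labels are
  used, not that it is fully unsupervised end to end.
* Non-square micrographs are resized anisotropically to the square working
  frame; extreme aspect ratios will distort particles and degrade the
  radius filter.
* The ~4% area target is a dataset-level statistic; micrographs with
  strongly atypical particle density are better served by overriding
  `target_fraction`.
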