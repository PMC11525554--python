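# Methods

## Model

A tissue domain (TD) is modeled as a cluster in molecular feature space —
marker channels for mIF, reduced expression components for ST — whose
centroid is shared by every slide in a cohort. The pipeline assumes that
after per-slide normalization the same biology occupies the same region of
feature space on every slide, so a single k-means model over pooled
pixels/spots yields domains with consistent identity. Spatial coherence is
injected only through smoothing (Gaussian blur of image planes,
neighborhood averaging of spot components); the clustering itself is
spatially agnostic. This trades spatial modeling power for the ability to
fit dozens of specimens at once and to apply the fitted model to new
slides.

## mIF preprocessing

Per slide: 8-bit intensities are scaled to `[0, 1]`; planes are
downsampled by block averaging (edge blocks average only the pixels they
cover, so border tissue is preserved); a tissue mask is computed; channels
are log-mean normalized; planes are Gaussian smoothed. The mask gates only
subsampling and assignment — normalization statistics use the whole
downsampled image, with `mu` defined over the strictly positive pixels of
a channel so that sparse markers are not dragged toward zero by empty
background.

`y = log10(x / mu + 1)` is exactly invariant to a per-slide, per-channel
multiplicative gain because `mu` scales with the gain. The implementation
evaluates the ratio as `(x * n) / s` (`n` positive-pixel count, `s` their
sum) so only one rounding occurs; when a gain scales the pixel values and
their sums exactly in floating point — true for the 12-bit-quantized
synthetic data and gains such as 0.5, 2 or 10 — the normalized planes,
masks and labels are *bitwise* identical, and the test suite asserts this.

Gaussian smoothing uses a kernel truncated at 4 SD with reflection
boundaries (documented because the choice affects reproducibility at
tissue borders); `sigma` is in downsampled pixels and `sigma = 0` disables
smoothing. Masking clusters the per-pixel channel vectors (after an
internal normalize + smooth pass on the individual image) into two groups
with seeded 10-restart 2-means; the cluster whose center is dimmer after
Z-normalizing the two centers per channel is background. All-zero channels
are flagged, passed through normalization unchanged, and excluded from the
masking features.

## ST preprocessing

Counts from all slides are stacked, scaled to the median per-spot total,
log1p-transformed and reduced by mean-centered PCA (the normalization is
the dominant convention of this ecosystem and is configurable). Batch
correction is a pluggable hook applied after reduction and before
smoothing; the default subtracts each batch's centroid and adds the global
centroid — a rigid shift that removes first-order offsets while leaving
within-batch geometry untouched, chosen so the pipeline has no heavyweight
external dependency; any algorithm with the same shape-preserving contract
can be plugged in. Spot smoothing averages each spot's components over its
hexagonal neighborhood, computed directly from Visium array coordinates
(6-adjacency: row ±1 / col ±1 and col ±2; positions satisfy
`(row + col) % 2 == 0`). The neighborhood includes the central spot so
`n_rings = 0` is the identity, and never crosses slides.

## Consensus labeling

Fitting pools `floor(0.2 * N_mask)` uniformly drawn in-mask pixels per mIF
slide (all spots for ST), Z-normalizes the pool with population (1/N) SD —
the divisor is fixed and documented for reproducibility — and runs
k-means (k-means++, best of `n_init = 10` restarts, `max_iter = 300`,
tolerance 1e-4, seeded) for each k in the search range. Zero-variance
features are dropped with a warning rather than imputed, since their
Z-score is undefined.

k is chosen by minimizing `adjusted(k) = inertia(k) / inertia(1) + alpha*k`.
Dividing by `inertia(1)` (the total sum of squares, computed in closed
form) makes the curve scale-free so `alpha` is comparable across datasets;
the linear penalty makes smaller `alpha` select more clusters. Ties go to
the smaller k. A fixed-k mode bypasses selection for benchmarks where the
domain count is prescribed. Assignment maps every in-mask pixel/spot into
Z-space with the *stored subsample* mean/SD and takes the nearest centroid
(ties to the lowest index); background is `-1`. Domain profiles
un-Z-normalize the centroids back to input units, and for ST can be
back-projected through the stored PCA loadings plus center into gene
space.

## QC

Confidence per pixel is `(d2 - d1) / d2` with `d1`, `d2` the distances to
the assigned and second-closest centroids: 1 exactly at a centroid, 0 at
an equidistant point, invariant under isometries of Z-space. Duplicate
centroids (excluded by the model invariant) would defensively yield 0 with
a warning. Slide-level variance explained is `1 - SS_within / SS_total`
computed in Z-space — the space the clustering optimizes — with
`SS_total` around the slide's own mean, since the metric is a per-slide
fit diagnostic; MSE is `SS_within / n`.

## Downstream statistics

Domain proportions are over in-mask pixels and sum to 1. Connected
components use `scipy.ndimage.label`; connectivity defaults to
4-neighborhood (the cross-shaped structuring element that labeling
function defaults to) with 8-connectivity exposed. Statistics restrict
correctly to a region-of-interest mask. The association modeling of
proportions / component sizes against sample groups is exported as a tidy
TSV for external statistical software rather than fitted here.

Signature scores are the mean log-normalized expression over a gene set
minus the mean over a seeded control pool drawn from expression-matched
bins (default 25 bins, 50 controls per signature gene); the pool may
include set genes, so a set spanning whole bins scores exactly zero — with
few genes choose few, wide bins so pools mix set and non-set genes.
Annotations are the argmax signature, ties to the first in input order.
Per-sample ARI uses the standard permutation-model form; consensus ARI
concatenates labels across samples first, so label identities swapped
between samples are penalized even when every per-sample ARI is 1.

## Synthetic cohorts

The mIF generator plants `k_true` contiguous domains per slide as a seeded
Voronoi tessellation of a tissue rectangle inside a zero background ring;
a few Lloyd relaxation steps make the domains organic but comparably
sized, so no planted domain is vanishingly small. Default profiles give
every channel between-domain contrast: a nuclear-like channel bright in
all tissue at domain-dependent density, one dominant marker channel per
domain (13/16), and a ubiquitous 3/16 baseline that keeps tissue clearly
above background in every channel, as matrix/autofluorescence signal does
in real panels. Slides apply multiplicative channel gains (the batch
effect normalization must remove) and additive Gaussian noise
(`noise_sd = 0.025`, i.e. domain separation an order of magnitude above
noise, representing a well-stained panel); intensities are clipped at 0
and quantized to a 12-bit grid, emulating fixed scanner bit depth. The ST
generator plants contiguous domains on a full Visium lattice via the same
Voronoi construction in physical hex coordinates, with Poisson counts from
per-domain programs (8× marker blocks over a uniform baseline) and
per-slide library scaling.

What the fixtures do **not** emulate: irregular tissue outlines, spatially
varying illumination, autofluorescence structure, cell-scale texture,
zero-inflated or overdispersed counts, and partial-overlap domain
compositions. Passing recovery tests therefore demonstrates the pipeline's
mechanics (batch removal, pooling, k-selection, assignment), not
performance on real histology.

Simulation sizes were chosen to keep the full suite fast while leaving the
statistics stable: 3 slides of 128 × 128 pixels (≈ 35k tissue pixels) for
recovery runs, 64 × 64 for exactness checks, 40 × 40 lattices (800 spots
per slide) for ST. The recovery runs use `downsample_factor = 1` and
`sigma = 0.5`: the fixtures are already low-resolution (whole-slide scans
are where factors of 8–32 apply), and at this scale a larger blur radius
mixes the zero background into a border halo that is an artifact of the
small frame rather than a property of the method.

## Known limitations

k-means assumes roughly isotropic clusters in Z-space; strongly
non-Euclidean marker structure can produce unstable domains (the QC
metrics are the intended detector). Smoothing lowers effective resolution,
so small heterogeneous domains can be absorbed by neighbors. The default
batch hook removes only mean shifts; residual higher-order batch structure
requires an external harmonization algorithm behind the same contract.
The adjusted-inertia elbow can over-split when a large fraction of pixels
is intermediate between domains (e.g. heavy blur), which is why `sigma`
should scale with the data's resolution.
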