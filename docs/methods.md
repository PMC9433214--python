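# Methods

This note documents the models, parameter choices and numerical
conventions behind `swarmseg`: a comparative framework for intensity-based
medical-image segmentation with six scenarios — fuzzy C-means (FCM),
K-means, each seeded by particle-swarm optimization (PSO), and each
refined by a small convolutional network (CNN) — evaluated with a
nine-score metric suite on synthetic phantoms with exact ground truth.

## Phantom model

Real acquisition modalities (MRI tumours, dermoscopic lesions, stained
nuclei, lung CT) challenge intensity clustering through a bright compact
foreground on a darker background, uneven illumination, heavy noise and —
in dermoscopy — dark occluding hair.  A phantom reproduces exactly these
features with a known mask:

1. **Blobs.** `n_blobs` random ellipses (uniform centre, semi-axes in
   [side/8, side/3], uniform rotation, re-drawn until fully in frame)
   painted at `blob_intensity_mean` over a flat
   `background_intensity_mean`.  The truth mask is the blob union at this
   stage.  The axis range makes one blob cover roughly 10–30 % of the
   frame, as in lesion-centred crops; a much smaller foreground would make
   two-cluster intensity segmentation ill-posed by construction (the
   optimal two-cluster split of the histogram would divide the background
   noise instead of separating the lesion).
2. **Illumination.** A linear left-to-right multiplicative ramp,
   `1 − g·x/(W−1)` with `g = illumination_gradient ∈ [0, 1]`.
3. **Noise.** Additive Gaussian noise with standard deviation
   `noise_sigma` (8-bit intensity units).
4. **Hair.** `hair_count` cubic Bézier curves, 1–3 px wide, painted at
   intensity 15 over the image only — never into the mask.
5. Clipping to [0, 255] and rounding half-up to `uint8`.

The three corruption stages draw from independent child RNG streams of the
spec seed, so the same seed with and without hair (or noise) renders the
identical underlying scene — which is what the paired preprocessing tests
rely on.  Per-sample seeds in benchmark sets are derived from the master
seed by a counter scheme (`SeedSequence([master, set_idx, sample_idx])`),
so membership does not depend on generation order.

Defaults (256×256 canvas, blob 180 on background 60, noise σ = 15, ramp
0.2, no hair) are this package's own choice of a "moderately hard"
phantom; the modality presets (`skin`, `mri`, `micro`, `ct`) only shift
these parameters in the direction of each modality's salient difficulty
and make no claim of matching any real dataset's intensity statistics.

What phantoms do *not* emulate: anatomical texture, partial-volume
boundaries, multiplicative speckle, 3-D context, annotation noise.
Passing on phantoms demonstrates algorithmic correctness and the relative
behaviour of the six scenarios under controlled corruption — not clinical
performance.

## Preprocessing

* **Grayscale.** `G = 0.3 R + 0.59 G + 0.11 B`, rounded half-up.  All
  intensity-valued formulas in the package round half-up to the nearest
  integer — one fixed 8-bit convention.
* **Contrast enhancement** is clip-limited adaptive histogram
  equalization: the image is tiled (default 8×8), each tile's 256-bin
  histogram is clipped at `clip_limit_multiplier` (default 4) times the
  tile's average bin occupancy (tile pixels / bins), the clipped excess is
  redistributed uniformly, tiles are equalized through their clipped CDF
  (`255·(cdf − cdf_min)/(N − cdf_min)`), and per-tile mappings are blended
  bilinearly between tile centres.  Conventions: a constant tile maps
  identically (a single-spike histogram is not redistributed), and with an
  infinite clip limit and a single tile the operator reduces exactly to
  plain histogram equalization (verified against an independent
  implementation in the tests).  Each per-tile mapping is monotone
  non-decreasing because it is a scaled CDF.
* **Hair removal.** Black-tophat (disk radius 5) on the luminance channel,
  thresholded at `max(Otsu, 30)` — the absolute floor of 30 intensity
  units keeps unimodal noise responses from triggering a false detection —
  with connected components under 30 px discarded and the mask dilated by
  1 px.  Detected pixels are replaced by their nearest non-hair neighbour
  and smoothed (Gaussian σ = 2) inside the mask only.  This
  nearest-neighbour inpainting is cheap, deterministic and sufficient for
  1–3 px curves; it does not reconstruct texture under wide occlusions.

A deliberate consequence worth stating plainly: *local* equalization
removes *global* intensity differences.  On piecewise-constant phantoms,
tiles lying entirely inside the lesion and entirely in the background end
up with near-identical output histograms, so two-cluster intensity
clustering after enhancement degrades sharply under heavy noise.  The
benchmark applies the same front-end to all six scenarios, so the
comparison is fair, and this is precisely the regime where the learned
refinement shows its value; `RunConfig(enhance=False)` disables the step.

## Clustering cores

Both cores operate on per-pixel grayscale intensity (1-D feature space).

**FCM** minimises `J = Σ_i Σ_j μ_ij^k (x_i − c_j)²` (`k > 1`, default 2)
by alternating the membership update
`μ_ij = 1 / Σ_m (|x_i − c_j| / |x_i − c_m|)^(2/(k−1))`
with the centre update `c_j = Σ μ^k x / Σ μ^k`, stopping when the largest
centre displacement drops below `tol` (default 1e-4) or after `max_iter`
(default 100).  A pixel coinciding with a centre takes the hard-assignment
limit (the update's continuous limit as the distance vanishes).
Duplicate centres raise an error at the membership level.

**K-means** is Lloyd iteration with the same stopping rule; an emptied
cluster is re-seeded to the intensity farthest from its centre, which
strictly lowers the inertia.

Implementation detail: because intensities take at most 256 distinct
values, both solvers iterate over the histogram (unique values weighted by
counts) — an exact reformulation that makes a sweep O(values × clusters)
and keeps the PSO fitness cheap.  Initial centres are distinct intensity
values sampled with probability proportional to their pixel counts (i.e.
random pixels), from the seeded generator.

**Mask extraction** takes the cluster with the brightest centre (argmax
membership first for FCM) as foreground — tumours, lesions and nuclei are
bright-on-dark after enhancement; a `darkest` switch covers the inverse —
then keeps the largest connected component and fills holes.  An empty
post-processed mask issues a warning rather than an error.

## PSO hybrids

A particle's position is a candidate centre vector (dimension =
n_clusters, clamped to [0, 255]); its fitness is the clustering objective
itself — K-means inertia or the FCM error with memberships induced by the
candidate centres.  The update is the standard inertia-weighted rule
`V ← wV + c1 r1 (pbest − P) + c2 r2 (gbest − P)`, `P ← P + V`, with fresh
uniform draws per component, velocity clamped to ± the full intensity
range, and defaults w = 0.72, c1 = c2 = 1.49, 30 particles, 100
iterations (standard constriction-equivalent values).  Two further
choices: positions are kept **sorted** after every move, collapsing the
k! label-permutation symmetry of the search space; and near-duplicate
components (within 1e-9) receive a large finite penalty instead of an
exception, so the swarm can move off the degenerate set.  The winning
vector then seeds a final FCM/Lloyd refinement, which by construction
cannot increase the objective.

On noiseless phantoms the hybrids recover the generating intensity levels
to well under 0.5 units, and on exhaustively enumerable 12-pixel instances
they reach the global two-cluster optimum for every tested seed — PSO
seeding buys robustness to bad initialisation rather than a better
optimum on these easy landscapes.

## CNN mask refinement

The two deep hybrids feed (grayscale image, clustering-proposed mask) as a
2-channel 128×128 tile into a compact encoder–decoder (three 2× max-pool
stages over 3×3 convolutions of width 8/16/32, a bottleneck, three
nearest-neighbour upsampling stages, ~21k parameters) ending in a 1×1 head
over the last feature block concatenated with the raw input.  The head is
initialised to *copy the proposal channel* (weight 12, bias −6 on the
skip), so the untrained network already reproduces the clustering mask and
training moves away from that identity only where the loss rewards it;
this also makes the identity shortcut trivially learnable when proposals
equal the truth.  The loss is `0.5·(1 − softDice) + 0.5·BCE`, optimised
with Adam (lr 1e-3, batch 4, default 10 epochs, 20 % validation split).

The network is implemented directly in numpy: im2col matrix-multiply
convolutions, input gradients as convolutions with spatially flipped
kernels (no scatter-adds), analytic gradients verified against finite
differences.  This keeps training deterministic given the seed,
dependency-free and fast (tens of seconds for 50 tiles × 10 epochs on one
CPU).  Checkpoints are `.npz` archives that reload to bit-identical
forward passes.

Probability maps are resized back to the input resolution (bilinear) and
thresholded at 0.5; raising the threshold can only shrink the foreground.

## Metrics

Foreground is the positive class.  From the pixel confusion table:
precision, recall, F-measure, accuracy % (and error % = 100 − accuracy),
MCC, Dice `2TP/(2TP+FP+FN)` and Jaccard `TP/(TP+FP+FN)`; wall time is
captured around the segmentation call only.  Conventions: any 0/0 ratio
and a zero MCC denominator report 0 (logged), keeping aggregation total.
Benchmark tables report **per-image means** within each method × set-size
cell, not pooled pixel counts.

## Benchmark and problem sizes

The shipped comparison (`scripts/acceptance.py`, also exercised by the
test suite) runs all six methods on 30 freshly generated 256×256 phantoms
at noise σ = 25 and illumination drop 0.3, with both refiners trained
in-run on 50 phantoms for 10 epochs — sizes chosen so the full comparison
completes in a few minutes on one CPU while leaving the ordering of
method families stable across seeds.  Under these conditions the CNN
hybrids reach mean Dice ≈ 0.9 while the traditional and PSO variants sit
far lower (the enhancement interaction described above), and the PSO
variants essentially tie their plain counterparts because both converge
to the same objective optimum — the swarm's contribution is initialisation
robustness, which these unimodal 1-D landscapes rarely need.

## Known limitations

* Intensity-only features: no spatial regularisation inside the
  clustering; spatially interleaved classes with equal intensities are
  out of reach by design.
* The refiners are trained on phantoms; shipped behaviour on real medical
  images is undefined and no pretrained clinical weights are provided.
* Nearest-neighbour hair inpainting blurs texture under the removed curve.
* Wall-clock columns are hardware-dependent and excluded from all
  reproducibility comparisons.
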