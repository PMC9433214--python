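# swarmseg

Comparative intensity-clustering segmentation for 2-D medical-style
images: fuzzy C-means (FCM) and K-means cores, particle-swarm-seeded
hybrids, and CNN-refined hybrids, with shared preprocessing (luminance
grayscale, clip-limited adaptive histogram equalization, dermoscopic hair
removal), a nine-score evaluation suite and a benchmark harness.  Because
the package ships a phantom generator with exact ground truth, every
method is testable end-to-end without downloading any dataset.

It is aimed at researchers comparing classical, swarm-optimised and
learned segmentation stages under controlled corruption (noise, uneven
illumination, occluding hair), and at anyone needing a small, fully
deterministic, dependency-light reference implementation of these methods.

## The methods

**FCM** minimises the fuzzified squared error over pixel intensities
`x_i` and cluster centres `c_j`,

    J = Σ_i Σ_j μ_ij^k (x_i − c_j)²,
    μ_ij = 1 / Σ_m ( |x_i − c_j| / |x_i − c_m| )^(2/(k−1)),

alternating membership and centre updates (`k > 1` controls softness).
**K-means** is Lloyd iteration on the same 1-D intensity feature.
**PSO hybrids** search the space of centre vectors with the standard
particle-swarm update

    V ← w·V + c1·r1·(pbest − P) + c2·r2·(gbest − P),    P ← P + V,

using the clustering objective itself as fitness, then refine the winning
centres with FCM/Lloyd.  **CNN hybrids** feed (image, proposed mask) into
a small encoder–decoder trained with a Dice + cross-entropy loss to
predict the true mask, learning the systematic errors of the clustering
stage.  Predictions are scored with precision, recall, F-measure,
accuracy/error %, MCC, Dice `2TP/(2TP+FP+FN)` and Jaccard
`TP/(TP+FP+FN)`.

See `docs/methods.md` for assumptions, parameter defaults and numerical
conventions.

## Worked example

```python
import numpy as np
from swarmseg import (PhantomSpec, generate_phantom, kmeans_segment,
                      partition_to_mask, confusion, score)

spec = PhantomSpec(width=256, height=256, blob_intensity_mean=180,
                   background_intensity_mean=60, noise_sigma=15,
                   illumination_gradient=0.2, seed=42)
sample = generate_phantom(spec)

part = kmeans_segment(sample.image, n_clusters=2, seed=0)
mask = partition_to_mask(part, sample.image)
rep = score(confusion(mask, sample.truth_mask))
print(f"k-means centers: {np.round(part.centers, 2)}")
print(f"Dice: {rep.dice:.4f}  MCC: {rep.mcc:.4f}  accuracy: {rep.accuracy_pct:.2f}%")
```

prints

```
k-means centers: [ 54.52 152.86]
Dice: 0.9999  MCC: 0.9999  accuracy: 100.00%
```

The recovered centres sit below the generating means (60/180) because the
illumination ramp darkens the right side of the frame; the mask still
matches the ground-truth blob almost pixel-perfectly (Dice 0.9999), since
the two intensity populations stay separable at this noise level.

## Command line

```bash
swarmseg phantoms --count 20 --out data/ --seed 1 --modality skin
swarmseg run --method kmeans --method kmeans-cnn --counts 30 --seed 1 --out results/
swarmseg train-cnn --proposal kmeans --count 50 --epochs 10 --out model.npz
swarmseg score --pred preds/ --truth truths/
swarmseg segment data/phantom_0000.png --method kmeans --out mask.png
```

`swarmseg run` writes per-image masks, a long-format metric CSV, an
aggregated summary, a wide method-comparison pivot and a JSON manifest;
every output except wall-clock timings is byte-reproducible from
(config, seed).

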