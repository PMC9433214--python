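"""Intensity-domain clustering cores: fuzzy C-means and K-means.

Both methods cluster the per-pixel grayscale intensity (a 1-D feature
space).  Fuzzy C-means minimises the fuzzified squared-error objective

    J = sum_i sum_j  mu_ij^k  (x_i - c_j)^2,        k > 1,

by alternating the membership update

    mu_ij = 1 / sum_m ( |x_i - c_j| / |x_i - c_m| )^(2/(k-1))

with the weighted centre update  c_j = sum_i mu_ij^k x_i / sum_i mu_ij^k.
K-means is Lloyd iteration on the same feature space (hard assignment to
the nearest centre, centres recomputed as member means).

Because the feature is a single 8-bit intensity, both solvers operate on
the histogram of unique values with pixel counts as weights — an exact
reformulation of the per-pixel iteration that makes each sweep O(#distinct
values x #clusters) instead of O(#pixels x #clusters).  Public outputs
(membership matrices, label maps) are expanded back to per-pixel shape.

Estimators follow the scikit-learn protocol (``fit`` on a 2-D image,
fitted attributes with trailing underscores, ``get_params``/``set_params``
inherited from ``BaseEstimator``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as connected_label
from sklearn.base import BaseEstimator

__all__ = [
    "DegenerateInputError",
    "DegenerateCentersError",
    "EmptyROIWarning",
    "FuzzyPartition",
    "HardPartition",
    "fcm_membership",
    "fcm_objective",
    "fcm_segment",
    "kmeans_segment",
    "partition_to_mask",
    "FCMSegmenter",
    "KMeansSegmenter",
]

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """The image cannot support the requested clustering."""


class DegenerateCentersError(ValueError):
    """Two or more cluster centres coincide."""


class EmptyROIWarning(UserWarning):
    """Post-processing removed every foreground pixel."""


@dataclass
class FuzzyPartition:
    """Converged FCM state: memberships mu_ij, centres, and the objective."""

    memberships: np.ndarray  # (n_pixels, n_clusters), rows sum to 1
    centers: np.ndarray
    fuzziness: float
    objective: float
    iterations_run: int
    objective_trace: list[float] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


@dataclass
class HardPartition:
    """Converged K-means state: per-pixel labels, centres, inertia."""

    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    iterations_run: int
    inertia_trace: list[float] = field(default_factory=list)


def _as_intensities(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def fcm_membership(
    intensities: np.ndarray, centers: np.ndarray, fuzziness: float = 2.0
) -> np.ndarray:
    """Fuzzy membership matrix of each intensity w.r.t. each centre.

    A pixel coinciding with a centre takes the hard-assignment limit
    (membership 1 there, 0 elsewhere), which is the continuous limit of the
    update as the distance goes to zero.
    """
    x = _as_intensities(intensities)
    c = np.asarray(centers, dtype=float).ravel()
    if c.size < 2:
        raise DegenerateCentersError(f"need >= 2 centers, got {c.size}")
    if fuzziness <= 1:
        raise ValueError(f"fuzziness must be > 1, got {fuzziness}")
    diffs = np.abs(c[None, :] - c[:, None])
    if np.any(diffs[np.triu_indices(c.size, k=1)] < 1e-12):
        raise DegenerateCentersError(f"duplicate centers in {c}")

    d = np.abs(x[:, None] - c[None, :])  # (n, k)
    power = 2.0 / (fuzziness - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-power)
        mu = inv / inv.sum(axis=1, keepdims=True)
    coincident = d == 0
    hit = coincident.any(axis=1)
    if hit.any():
        mu[hit] = coincident[hit].astype(float)
    return mu


def fcm_objective(
    intensities: np.ndarray,
    memberships: np.ndarray,
    centers: np.ndarray,
    fuzziness: float = 2.0,
    weights: np.ndarray | None = None,
) -> float:
    """Fuzzified squared-error objective sum mu^k (x - c)^2."""
    x = _as_intensities(intensities)
    c = np.asarray(centers, dtype=float).ravel()
    mu = np.asarray(memberships, dtype=float)
    sq = (x[:, None] - c[None, :]) ** 2
    terms = (mu**fuzziness) * sq
    if weights is not None:
        terms = terms * np.asarray(weights, dtype=float)[:, None]
    return float(terms.sum())


def _compress(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique intensities, per-value pixel counts, and inverse indices."""
    values, inverse, counts = np.unique(
        np.asarray(img, dtype=float).ravel(), return_inverse=True, return_counts=True
    )
    return values, counts.astype(float), inverse


def _init_centers(
    values: np.ndarray, counts: np.ndarray, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct random pixel intensities, weighted by occurrence."""
    centers = rng.choice(
        values, size=n_clusters, replace=False, p=counts / counts.sum()
    )
    return np.sort(centers)


class FCMSegmenter(BaseEstimator):
    """Fuzzy C-means segmentation of a grayscale image.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of intensity clusters (>= 2).
    fuzziness : float, default 2.0
        Membership softness exponent k > 1; k -> 1 approaches K-means.
    tol : float, default 1e-4
        Convergence threshold on the max centre displacement.
    max_iter : int, default 100
    random_state : int, default 0
        Seeds the centre initialisation (random distinct pixel intensities).
    init_centers : array-like or None
        Explicit initial centres; overrides random initialisation (used by
        the PSO hybrid to hand over its optimised centres).

    Attributes
    ----------
    centers_ : (n_clusters,) sorted converged centres
    memberships_ : (n_pixels, n_clusters) membership matrix
    labels_ : (n_pixels,) argmax-membership labels
    objective_ : converged objective value
    objective_trace_ : objective after every iteration (non-increasing)
    n_iter_ : iterations actually run
    """

    def __init__(
        self,
        n_clusters: int = 2,
        fuzziness: float = 2.0,
        tol: float = 1e-4,
        max_iter: int = 100,
        random_state: int = 0,
        init_centers=None,
    ):
        self.n_clusters = n_clusters
        self.fuzziness = fuzziness
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.init_centers = init_centers

    def fit(self, X: np.ndarray, y=None) -> "FCMSegmenter":
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        img = np.asarray(X)
        values, counts, inverse = _compress(img)
        if values.size < 2:
            raise DegenerateInputError(
                "image has a single distinct intensity; nothing to cluster"
            )
        if self.n_clusters > values.size:
            raise DegenerateInputError(
                f"n_clusters={self.n_clusters} exceeds the "
                f"{values.size} distinct intensities"
            )
        k = self.fuzziness
        if self.init_centers is not None:
            centers = np.sort(np.asarray(self.init_centers, dtype=float).ravel())
            if centers.size != self.n_clusters:
                raise ValueError(
                    f"init_centers has {centers.size} components, "
                    f"expected {self.n_clusters}"
                )
        else:
            rng = np.random.default_rng(self.random_state)
            centers = _init_centers(values, counts, self.n_clusters, rng)

        trace: list[float] = []
        for iteration in range(1, self.max_iter + 1):
            mu = fcm_membership(values, centers, k)
            w_mu = counts[:, None] * mu**k
            denom = w_mu.sum(axis=0)
            new_centers = np.where(
                denom > 0, (w_mu * values[:, None]).sum(axis=0) / denom, centers
            )
            new_centers = np.sort(new_centers)
            mu = fcm_membership(values, new_centers, k)
            trace.append(fcm_objective(values, mu, new_centers, k, weights=counts))
            delta = np.max(np.abs(new_centers - centers))
            centers = new_centers
            if delta < self.tol:
                break

        self.centers_ = centers
        self.memberships_ = mu[inverse]
        self.labels_ = np.argmax(self.memberships_, axis=1)
        self.objective_ = trace[-1]
        self.objective_trace_ = trace
        self.n_iter_ = iteration
        self._shape = img.shape
        return self

    def partition_(self) -> FuzzyPartition:
        return FuzzyPartition(
            memberships=self.memberships_,
            centers=self.centers_,
            fuzziness=self.fuzziness,
            objective=self.objective_,
            iterations_run=self.n_iter_,
            objective_trace=self.objective_trace_,
        )


class KMeansSegmenter(BaseEstimator):
    """Lloyd K-means on per-pixel intensity.

    Empty clusters are re-seeded to the intensity farthest from its current
    centre, which strictly lowers the inertia.  Fitted attributes follow
    the scikit-learn naming: ``labels_``, ``centers_``, ``inertia_``,
    ``inertia_trace_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        tol: float = 1e-4,
        max_iter: int = 100,
        random_state: int = 0,
        init_centers=None,
    ):
        self.n_clusters = n_clusters
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.init_centers = init_centers

    def fit(self, X: np.ndarray, y=None) -> "KMeansSegmenter":
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        img = np.asarray(X)
        values, counts, inverse = _compress(img)
        if self.n_clusters > values.size:
            raise DegenerateInputError(
                f"n_clusters={self.n_clusters} exceeds the "
                f"{values.size} distinct intensities"
            )
        if self.init_centers is not None:
            centers = np.sort(np.asarray(self.init_centers, dtype=float).ravel())
            if centers.size != self.n_clusters:
                raise ValueError(
                    f"init_centers has {centers.size} components, "
                    f"expected {self.n_clusters}"
                )
        else:
            rng = np.random.default_rng(self.random_state)
            centers = _init_centers(values, counts, self.n_clusters, rng)

        trace: list[float] = []
        for iteration in range(1, self.max_iter + 1):
            sq = (values[:, None] - centers[None, :]) ** 2
            assign = np.argmin(sq, axis=1)
            new_centers = centers.copy()
            for j in range(self.n_clusters):
                sel = assign == j
                w = counts[sel]
                if w.sum() > 0:
                    new_centers[j] = np.average(values[sel], weights=w)
                else:  # re-seed to the farthest intensity
                    per_value = sq[np.arange(values.size), assign]
                    new_centers[j] = values[np.argmax(per_value)]
            new_centers = np.sort(new_centers)
            sq = (values[:, None] - new_centers[None, :]) ** 2
            assign = np.argmin(sq, axis=1)
            trace.append(
                float((counts * sq[np.arange(values.size), assign]).sum())
            )
            delta = np.max(np.abs(new_centers - centers))
            centers = new_centers
            if delta < self.tol:
                break

        self.centers_ = centers
        self.labels_ = assign[inverse]
        self.inertia_ = trace[-1]
        self.inertia_trace_ = trace
        self.n_iter_ = iteration
        self._shape = img.shape
        return self

    def partition_(self) -> HardPartition:
        return HardPartition(
            labels=self.labels_,
            centers=self.centers_,
            inertia=self.inertia_,
            iterations_run=self.n_iter_,
            inertia_trace=self.inertia_trace_,
        )


def fcm_segment(
    img: np.ndarray,
    n_clusters: int = 2,
    fuzziness: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int = 0,
    init_centers=None,
) -> FuzzyPartition:
    """Functional wrapper over :class:`FCMSegmenter`."""
    est = FCMSegmenter(
        n_clusters=n_clusters,
        fuzziness=fuzziness,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
        init_centers=init_centers,
    ).fit(img)
    return est.partition_()


def kmeans_segment(
    img: np.ndarray,
    n_clusters: int = 2,
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int = 0,
    init_centers=None,
) -> HardPartition:
    """Functional wrapper over :class:`KMeansSegmenter`."""
    est = KMeansSegmenter(
        n_clusters=n_clusters,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
        init_centers=init_centers,
    ).fit(img)
    return est.partition_()


def partition_to_mask(
    partition: FuzzyPartition | HardPartition,
    img: np.ndarray,
    select: str = "brightest",
    keep_largest: bool = True,
    fill_holes: bool = True,
) -> np.ndarray:
    """Turn a partition into a binary region-of-interest mask.

    The foreground is the cluster whose centre is brightest (configurable
    to darkest, e.g. for dark-on-light microscopy); the largest connected
    component is retained and its holes filled.  If post-processing leaves
    no foreground an :class:`EmptyROIWarning` is issued and the (empty)
    mask returned as-is.
    """
    img = np.asarray(img)
    labels = (
        partition.labels if isinstance(partition, HardPartition) else partition.labels
    )
    centers = np.asarray(partition.centers, dtype=float).ravel()
    if select == "brightest":
        fg_cluster = int(np.argmax(centers))
    elif select == "darkest":
        fg_cluster = int(np.argmin(centers))
    else:
        raise ValueError(f"select must be 'brightest' or 'darkest', got {select!r}")

    mask = (labels == fg_cluster).reshape(img.shape[:2])
    if keep_largest and mask.any():
        comps = connected_label(mask, connectivity=2)
        sizes = np.bincount(comps.ravel())
        sizes[0] = 0
        mask = comps == np.argmax(sizes)
    if fill_holes and mask.any():
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        warnings.warn("post-processed ROI is empty", EmptyROIWarning, stacklevel=2)
    return mask
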