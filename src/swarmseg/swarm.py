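"""Particle-swarm search over cluster-centre vectors, and the two hybrids.

A particle's position is a candidate vector of cluster centres (one
component per cluster, clamped to the 8-bit intensity range).  Velocities
follow the standard update

    V <- w V + c1 r1 (pbest - P) + c2 r2 (gbest - P),     P <- P + V,

with fresh uniform(0,1) draws r1, r2 per component, positions clamped to
the bounds and velocities clamped to +/- the full bound range.  The fitness
a particle minimises is the clustering objective itself: K-means inertia
under nearest-centre assignment, or the fuzzy C-means error with
memberships induced by the candidate centres.  Positions are kept sorted
after every move, which removes the label-permutation plateaus from the
search space.

The hybrids run PSO first and then hand the winning centre vector to a
final FCM / Lloyd refinement, which can only lower the objective further.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator

from .clustering import (
    FuzzyPartition,
    HardPartition,
    fcm_membership,
    fcm_objective,
    fcm_segment,
    kmeans_segment,
    partition_to_mask,
    _compress,
)

__all__ = [
    "Particle",
    "SwarmState",
    "PSOParams",
    "fitness",
    "pso_optimize",
    "fcm_pso_segment",
    "kmeans_pso_segment",
    "PSOFCMSegmenter",
    "PSOKMeansSegmenter",
]

INTENSITY_BOUNDS = (0.0, 255.0)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class PSOParams:
    """Swarm hyperparameters (constriction-equivalent defaults)."""

    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    n_particles: int = 30
    max_iter: int = 100


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int
    hyperparams: PSOParams
    gbest_trace: list[float] = field(default_factory=list)


def _duplicate_count(position: np.ndarray, tol: float = 1e-9) -> int:
    p = np.sort(np.asarray(position, dtype=float).ravel())
    return int(np.sum(np.diff(p) < tol))


def fitness(
    position: np.ndarray,
    intensities: np.ndarray,
    mode: str = "kmeans",
    fuzziness: float = 2.0,
    weights: np.ndarray | None = None,
) -> float:
    """Clustering objective of a candidate centre vector (lower is better).

    Duplicate components (within 1e-9) receive a heavy but finite penalty
    instead of an exception, so the swarm can move away from them.
    """
    pos = np.asarray(position, dtype=float).ravel()
    x = np.asarray(intensities, dtype=float).ravel()
    if weights is None:
        weights = np.ones_like(x)
    w = np.asarray(weights, dtype=float).ravel()
    total = w.sum()

    dupes = _duplicate_count(pos)
    if dupes:
        return float(255.0**2 * total * (1 + dupes))

    if mode == "kmeans":
        sq = (x[:, None] - pos[None, :]) ** 2
        return float((w * sq.min(axis=1)).sum())
    if mode == "fcm":
        mu = fcm_membership(x, pos, fuzziness)
        return fcm_objective(x, mu, pos, fuzziness, weights=w)
    raise ValueError(f"mode must be 'kmeans' or 'fcm', got {mode!r}")


def pso_optimize(
    fitness_fn: Callable[[np.ndarray], float],
    dim: int,
    bounds: tuple[float, float] = INTENSITY_BOUNDS,
    hyperparams: PSOParams | None = None,
    seed: int = 0,
    sort_positions: bool = False,
) -> SwarmState:
    """Minimise ``fitness_fn`` over a ``dim``-dimensional box.

    Returns the final swarm state including the per-iteration global-best
    fitness trace (always non-increasing).  NaN or infinite fitness aborts
    with a diagnostic naming the particle and iteration.
    """
    hp = hyperparams or PSOParams()
    if hp.n_particles < 2:
        raise ValueError(f"n_particles must be >= 2, got {hp.n_particles}")
    if hp.max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {hp.max_iter}")
    lo, hi = float(bounds[0]), float(bounds[1])
    if not hi > lo:
        raise ValueError(f"bounds must satisfy hi > lo, got {bounds}")
    span = hi - lo
    rng = np.random.default_rng(seed)

    def _eval(pos: np.ndarray, p_idx: int, it: int) -> float:
        val = float(fitness_fn(pos))
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite fitness {val} for particle {p_idx} at iteration {it}"
            )
        return val

    particles: list[Particle] = []
    for i in range(hp.n_particles):
        pos = rng.uniform(lo, hi, size=dim)
        if sort_positions:
            pos = np.sort(pos)
        vel = rng.uniform(-0.1 * span, 0.1 * span, size=dim)
        fit = _eval(pos, i, 0)
        particles.append(Particle(pos, vel, pos.copy(), fit))

    best = int(np.argmin([p.pbest_fitness for p in particles]))
    gbest_pos = particles[best].pbest_position.copy()
    gbest_fit = particles[best].pbest_fitness
    trace = [gbest_fit]

    for it in range(1, hp.max_iter + 1):
        for i, p in enumerate(particles):
            r1 = rng.uniform(size=dim)
            r2 = rng.uniform(size=dim)
            p.velocity = (
                hp.inertia * p.velocity
                + hp.cognitive * r1 * (p.pbest_position - p.position)
                + hp.social * r2 * (gbest_pos - p.position)
            )
            np.clip(p.velocity, -span, span, out=p.velocity)
            p.position = np.clip(p.position + p.velocity, lo, hi)
            if sort_positions:
                p.position = np.sort(p.position)
            fit = _eval(p.position, i, it)
            if fit < p.pbest_fitness:
                p.pbest_fitness = fit
                p.pbest_position = p.position.copy()
                if fit < gbest_fit:
                    gbest_fit = fit
                    gbest_pos = p.position.copy()
        trace.append(gbest_fit)

    return SwarmState(
        particles=particles,
        gbest_position=gbest_pos,
        gbest_fitness=gbest_fit,
        iteration=hp.max_iter,
        hyperparams=hp,
        gbest_trace=trace,
    )


class PSOFCMSegmenter(BaseEstimator):
    """PSO-seeded fuzzy C-means: swarm search, then FCM refinement.

    Fitted attributes mirror :class:`~swarmseg.clustering.FCMSegmenter`
    plus ``swarm_`` (final swarm state) and ``pso_objective_`` (the best
    fitness found by the raw swarm, before refinement).
    """

    _mode = "fcm"

    def __init__(
        self,
        n_clusters: int = 2,
        fuzziness: float = 2.0,
        tol: float = 1e-4,
        max_iter: int = 100,
        pso_params: PSOParams | None = None,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.fuzziness = fuzziness
        self.tol = tol
        self.max_iter = max_iter
        self.pso_params = pso_params
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None):
        img = np.asarray(X)
        values, counts, _ = _compress(img)

        def fn(pos: np.ndarray) -> float:
            return fitness(
                pos, values, mode=self._mode, fuzziness=self.fuzziness, weights=counts
            )

        state = pso_optimize(
            fn,
            dim=self.n_clusters,
            bounds=INTENSITY_BOUNDS,
            hyperparams=self.pso_params,
            seed=self.random_state,
            sort_positions=True,
        )
        self.swarm_ = state
        self.pso_objective_ = state.gbest_fitness
        self.partition_obj_ = self._refine(img, state.gbest_position)
        self.centers_ = self.partition_obj_.centers
        return self

    def _refine(self, img, centers) -> FuzzyPartition:
        part = fcm_segment(
            img,
            n_clusters=self.n_clusters,
            fuzziness=self.fuzziness,
            tol=self.tol,
            max_iter=self.max_iter,
            init_centers=centers,
        )
        self.objective_ = part.objective
        return part

    def partition_(self):
        return self.partition_obj_


class PSOKMeansSegmenter(PSOFCMSegmenter):
    """PSO-seeded K-means: swarm search, then Lloyd refinement."""

    _mode = "kmeans"

    def __init__(
        self,
        n_clusters: int = 2,
        tol: float = 1e-4,
        max_iter: int = 100,
        pso_params: PSOParams | None = None,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.tol = tol
        self.max_iter = max_iter
        self.pso_params = pso_params
        self.random_state = random_state
        self.fuzziness = 2.0  # unused in kmeans mode

    def _refine(self, img, centers) -> HardPartition:
        part = kmeans_segment(
            img,
            n_clusters=self.n_clusters,
            tol=self.tol,
            max_iter=self.max_iter,
            init_centers=centers,
        )
        self.objective_ = part.inertia
        return part


def fcm_pso_segment(
    img: np.ndarray,
    n_clusters: int = 2,
    fuzziness: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    pso_params: PSOParams | None = None,
    seed: int = 0,
    **mask_kwargs,
) -> tuple[FuzzyPartition, np.ndarray]:
    """PSO-seeded FCM segmentation; returns (partition, ROI mask)."""
    est = PSOFCMSegmenter(
        n_clusters=n_clusters,
        fuzziness=fuzziness,
        tol=tol,
        max_iter=max_iter,
        pso_params=pso_params,
        random_state=seed,
    ).fit(img)
    part = est.partition_()
    return part, partition_to_mask(part, img, **mask_kwargs)


def kmeans_pso_segment(
    img: np.ndarray,
    n_clusters: int = 2,
    tol: float = 1e-4,
    max_iter: int = 100,
    pso_params: PSOParams | None = None,
    seed: int = 0,
    **mask_kwargs,
) -> tuple[HardPartition, np.ndarray]:
    """PSO-seeded K-means segmentation; returns (partition, ROI mask)."""
    est = PSOKMeansSegmenter(
        n_clusters=n_clusters,
        tol=tol,
        max_iter=max_iter,
        pso_params=pso_params,
        random_state=seed,
    ).fit(img)
    part = est.partition_()
    return part, partition_to_mask(part, img, **mask_kwargs)
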