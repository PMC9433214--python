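"""FCM and K-means cores: formula fidelity, convergence, mask extraction."""

import itertools

import numpy as np
import pytest

from swarmseg.clustering import (
    DegenerateCentersError,
    DegenerateInputError,
    EmptyROIWarning,
    FuzzyPartition,
    fcm_membership,
    fcm_objective,
    fcm_segment,
    kmeans_segment,
    partition_to_mask,
)


class TestMembership:
    def test_equidistant_pixel_splits_evenly(self):
        mu = fcm_membership([50.0], [0.0, 100.0], 2.0)
        np.testing.assert_allclose(mu, [[0.5, 0.5]], atol=1e-12)

    def test_pixel_at_center_is_hard(self):
        mu = fcm_membership([0.0], [0.0, 100.0], 2.0)
        np.testing.assert_allclose(mu, [[1.0, 0.0]], atol=0)

    def test_hand_evaluated_ratio(self):
        # distances 25 and 75; ratio^2 terms give 1/(1 + (25/75)^2) = 0.9
        mu = fcm_membership([25.0], [0.0, 100.0], 2.0)
        np.testing.assert_allclose(mu, [[0.9, 0.1]], atol=1e-9)

    def test_rows_always_sum_to_one(self, rng):
        x = rng.uniform(0, 255, size=200)
        centers = [10.0, 90.0, 201.5]
        mu = fcm_membership(x, centers, 1.7)
        np.testing.assert_allclose(mu.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(mu >= 0) and np.all(mu <= 1)

    def test_duplicate_centers_rejected(self):
        with pytest.raises(DegenerateCentersError):
            fcm_membership([1.0], [5.0, 5.0], 2.0)


class TestObjective:
    def test_zero_at_centers(self):
        mu = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert fcm_objective([0.0, 100.0], mu, [0.0, 100.0], 2.0) == 0.0

    def test_single_pixel_value(self):
        assert fcm_objective([10.0], np.array([[1.0]]), [0.0], 2.0) == 100.0

    def test_quadratic_homogeneity(self, rng):
        x = rng.uniform(0, 50, size=20)
        centers = np.array([10.0, 40.0])
        mu = fcm_membership(x, centers, 2.0)
        j1 = fcm_objective(x, mu, centers, 2.0)
        j2 = fcm_objective(2 * x, mu, 2 * centers, 2.0)
        assert j2 == pytest.approx(4 * j1, rel=1e-9)


class TestFCMSegment:
    def test_recovers_two_level_centers(self, two_level_phantom):
        part = fcm_segment(two_level_phantom.image, n_clusters=2, seed=0)
        np.testing.assert_allclose(np.sort(part.centers), [40.0, 200.0], atol=0.5)

    def test_objective_trace_non_increasing(self, noisy_spec):
        from swarmseg.phantoms import generate_phantom

        img = generate_phantom(noisy_spec).image
        part = fcm_segment(img, n_clusters=3, seed=1)
        trace = np.array(part.objective_trace)
        assert np.all(np.diff(trace) <= 1e-6 * np.maximum(trace[:-1], 1.0))

    def test_objective_field_consistent_with_formula(self, two_level_phantom):
        part = fcm_segment(two_level_phantom.image, seed=0)
        recomputed = fcm_objective(
            two_level_phantom.image.ravel().astype(float),
            part.memberships,
            part.centers,
            part.fuzziness,
        )
        assert part.objective == pytest.approx(recomputed, abs=1e-6 * max(recomputed, 1))

    def test_deterministic_given_seed(self, noisy_spec):
        from swarmseg.phantoms import generate_phantom

        img = generate_phantom(noisy_spec).image
        a = fcm_segment(img, seed=3)
        b = fcm_segment(img, seed=3)
        np.testing.assert_array_equal(a.memberships, b.memberships)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_single_intensity_rejected(self):
        with pytest.raises(DegenerateInputError, match="single distinct intensity"):
            fcm_segment(np.full((8, 8), 7, dtype=np.uint8))


def _exhaustive_best_inertia(values: np.ndarray, k: int = 2) -> float:
    """Global 2-cluster optimum by enumerating every label assignment."""
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(values)):
        labels = np.array(labels)
        if len(set(labels.tolist())) < k:
            continue
        inertia = 0.0
        for j in range(k):
            sel = values[labels == j]
            inertia += ((sel - sel.mean()) ** 2).sum()
        best = min(best, inertia)
    return best


class TestKMeansSegment:
    def test_two_level_equals_midpoint_threshold(self, two_level_phantom):
        img = two_level_phantom.image
        part = kmeans_segment(img, n_clusters=2, seed=0)
        expected = (img.ravel() > (40 + 200) / 2).astype(int)
        labels = part.labels
        if part.centers[0] > part.centers[1]:
            labels = 1 - labels
        np.testing.assert_array_equal(labels, expected)

    def test_inertia_trace_non_increasing(self, noisy_spec):
        from swarmseg.phantoms import generate_phantom

        img = generate_phantom(noisy_spec).image
        part = kmeans_segment(img, n_clusters=3, seed=2)
        trace = np.array(part.inertia_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))

    def test_four_pixel_instance_exact(self):
        img = np.array([[0, 0], [100, 100]], dtype=np.uint8)
        part = kmeans_segment(img, n_clusters=2, seed=0)
        np.testing.assert_allclose(np.sort(part.centers), [0.0, 100.0])
        assert part.inertia == 0.0

    def test_centers_are_cluster_means(self, noisy_spec):
        from swarmseg.phantoms import generate_phantom

        img = generate_phantom(noisy_spec).image
        part = kmeans_segment(img, n_clusters=2, seed=0)
        flat = img.ravel().astype(float)
        for j, c in enumerate(part.centers):
            assert c == pytest.approx(flat[part.labels == j].mean(), abs=1e-6)

    def test_too_many_clusters_rejected(self):
        img = np.array([[0, 0], [100, 100]], dtype=np.uint8)
        with pytest.raises(DegenerateInputError):
            kmeans_segment(img, n_clusters=3)

    @pytest.mark.parametrize("seed", range(5))
    def test_local_optimality_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, size=10).astype(float)
        if len(np.unique(values)) < 2:
            values[0] += 1
        part = kmeans_segment(values.reshape(2, 5), n_clusters=2, seed=seed)
        # no single-pixel relabeling lowers the inertia
        labels = part.labels.copy()
        for i in range(len(values)):
            for j in range(2):
                if j == labels[i]:
                    continue
                trial = labels.copy()
                trial[i] = j
                inertia = 0.0
                for c in range(2):
                    sel = values[trial == c]
                    if len(sel):
                        inertia += ((sel - sel.mean()) ** 2).sum()
                assert inertia >= part.inertia - 1e-9


class TestPartitionToMask:
    def test_two_level_mask_matches_truth(self, two_level_phantom):
        part = kmeans_segment(two_level_phantom.image, seed=0)
        mask = partition_to_mask(part, two_level_phantom.image)
        truth = two_level_phantom.truth_mask
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.99

    def test_empty_roi_warns(self, two_level_phantom):
        part = kmeans_segment(two_level_phantom.image, seed=0)
        part.labels = np.zeros_like(part.labels)  # collapse to one cluster
        with pytest.warns(EmptyROIWarning):
            mask = partition_to_mask(part, two_level_phantom.image, select="brightest")
        assert not mask.any()

    def test_hard_membership_mask_is_blob(self, two_level_phantom):
        truth = two_level_phantom.truth_mask
        mu = np.zeros((truth.size, 2))
        mu[truth.ravel(), 1] = 1.0
        mu[~truth.ravel(), 0] = 1.0
        part = FuzzyPartition(
            memberships=mu, centers=np.array([40.0, 200.0]), fuzziness=2.0,
            objective=0.0, iterations_run=1,
        )
        mask = partition_to_mask(part, two_level_phantom.image)
        np.testing.assert_array_equal(mask, truth)

    def test_cluster_relabeling_does_not_change_mask(self, two_level_phantom):
        part = kmeans_segment(two_level_phantom.image, seed=0)
        mask_a = partition_to_mask(part, two_level_phantom.image)
        part.labels = 1 - part.labels
        part.centers = part.centers[::-1]
        mask_b = partition_to_mask(part, two_level_phantom.image)
        np.testing.assert_array_equal(mask_a, mask_b)

    def test_darkest_selection_inverts(self, two_level_phantom):
        part = kmeans_segment(two_level_phantom.image, seed=0)
        bright = partition_to_mask(part, two_level_phantom.image, select="brightest")
        dark = partition_to_mask(
            part, two_level_phantom.image, select="darkest",
            keep_largest=False, fill_holes=False,
        )
        assert not (bright & dark).any()
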