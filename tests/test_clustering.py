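"""PAM/CLARA k-medoids and prediction-strength model selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from engagetraj.clustering import (
    assign_to_medoids,
    clara,
    pam,
    prediction_strength,
    relabel_by_size,
)

SIX_POINTS = np.array([[0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]], float)


def exhaustive_kmedoids(x, k):
    """Brute-force optimum over all C(N, k) medoid sets."""
    d = cdist(x, x)
    best = min(
        (d[list(m)].min(axis=0).sum(), m) for m in itertools.combinations(range(len(x)), k)
    )
    return best  # (cost, medoid tuple)


class TestPam:
    def test_two_well_separated_triads(self):
        result = pam(SIX_POINTS, 2)
        assert set(result.medoid_indices) == {0, 3}
        assert result.total_cost == pytest.approx(4.0)
        cost, _ = exhaustive_kmedoids(SIX_POINTS, 2)
        assert result.total_cost == pytest.approx(cost)

    def test_k_equals_n_is_free(self):
        result = pam(SIX_POINTS, 6)
        assert result.total_cost == 0.0
        assert sorted(result.medoid_indices) == list(range(6))

    def test_k1_median_of_three(self):
        result = pam(np.array([0.0, 1.0, 2.0]), 1)
        assert result.medoid_indices[0] == 1
        assert result.total_cost == pytest.approx(2.0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            pam(SIX_POINTS, 0)
        with pytest.raises(ValueError):
            pam(SIX_POINTS, 7)

    def test_result_internally_consistent(self, rng):
        x = rng.normal(size=(40, 3))
        result = pam(x, 4)
        d = cdist(x[result.medoid_indices], x)
        assert np.array_equal(result.labels, d.argmin(axis=0) + 1)
        assert result.total_cost == pytest.approx(d.min(axis=0).sum())
        for pos, m in enumerate(result.medoid_indices):
            assert result.labels[m] == pos + 1

    @given(
        st.integers(2, 9).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.integers(1, min(3, n)),
                st.lists(
                    st.tuples(st.integers(0, 12), st.integers(0, 12)),
                    min_size=n,
                    max_size=n,
                ),
            )
        )
    )
    def test_swap_phase_contract_on_arbitrary_instances(self, case):
        """The fitted solution is single-swap locally optimal: no exchange of a
        medoid with a non-medoid strictly lowers the cost (PAM's stopping rule),
        the cost is recomputable, and it never beats the exhaustive optimum."""
        n, k, pts = case
        x = np.array(pts, float)
        result = pam(x, k)
        d = cdist(x, x)
        assert result.total_cost == pytest.approx(
            d[result.medoid_indices].min(axis=0).sum(), abs=1e-9
        )
        opt_cost, _ = exhaustive_kmedoids(x, k)
        assert result.total_cost >= opt_cost - 1e-9
        medoids = set(result.medoid_indices.tolist())
        for out in result.medoid_indices:
            for inn in range(n):
                if inn in medoids:
                    continue
                trial = sorted(medoids - {out} | {inn})
                assert d[trial].min(axis=0).sum() >= result.total_cost - 1e-9

    def test_matches_exhaustive_optimum_on_random_instances(self, rng):
        """On generic (tie-free) tiny instances PAM usually attains the
        brute-force optimum. Steepest-descent single-swap search does get
        trapped occasionally (R's cluster::pam lands in the same local optima
        on such instances), so gaps are logged and bounded rather than
        forbidden outright."""
        gaps = []
        for _ in range(250):
            n = int(rng.integers(3, 10))
            k = int(rng.integers(1, min(3, n - 1) + 1))
            x = rng.normal(size=(n, int(rng.integers(1, 3))))
            result = pam(x, k)
            opt_cost, _ = exhaustive_kmedoids(x, k)
            if result.total_cost > opt_cost + 1e-9:
                gaps.append((round(result.total_cost / opt_cost, 4), n, k))
            assert result.total_cost <= opt_cost * 1.5 + 1e-9, (n, k, x)
        assert len(gaps) <= 0.10 * 250, gaps
        if gaps:
            print(f"known-heuristic PAM gap instances (ratio, n, k): {gaps}")


class TestClara:
    def test_full_sample_single_draw_equals_pam_bitwise(self, rng):
        x = rng.normal(size=(50, 2))
        p = pam(x, 3)
        c = clara(x, 3, n_samples=1, sample_size=len(x), seed=99)
        assert np.array_equal(p.medoid_indices, c.medoid_indices)
        assert np.array_equal(p.labels, c.labels)
        assert p.total_cost == c.total_cost

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_six_point_fixture_recovered_for_any_seed(self, seed):
        result = clara(SIX_POINTS, 2, seed=seed)
        assert result.total_cost == pytest.approx(4.0)
        assert set(result.medoid_indices) == {0, 3}

    def test_two_large_1d_clusters_cost_close_to_pam(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 300), rng.normal(10, 0.1, 300)])
        full = pam(x, 2)
        sampled = clara(x, 2, seed=5)
        assert sampled.total_cost <= full.total_cost * 1.01

    def test_sample_size_below_k_rejected(self):
        with pytest.raises(ValueError):
            clara(SIX_POINTS, 3, sample_size=2)


class TestAssign:
    def test_exact_tie_goes_to_lowest_medoid(self):
        labels = assign_to_medoids(np.array([[5.0]]), np.array([[0.0], [10.0]]))
        assert labels[0] == 1

    def test_medoid_maps_to_itself(self):
        medoids = np.array([[0.0], [10.0]])
        assert assign_to_medoids(medoids, medoids).tolist() == [1, 2]

    def test_nearest_distance_rule(self):
        labels = assign_to_medoids(np.array([0.0, 4.0, 10.0]), np.array([0.0, 10.0]))
        assert labels.tolist() == [1, 1, 2]

    def test_empty_medoids_rejected(self):
        with pytest.raises(ValueError):
            assign_to_medoids(np.array([[0.0]]), np.zeros((0, 1)))


def brute_force_split_strength(x, train_idx, test_idx, k, seed_train, seed_test):
    """Independent oracle: explicit ordered-pair counting for one split."""
    ctrain = clara(x[train_idx], k, seed=seed_train)
    ctest = clara(x[test_idx], k, seed=seed_test)
    by_train = assign_to_medoids(x[test_idx], ctrain.medoids)
    worst = 1.0
    for j in range(1, k + 1):
        members = np.where(ctest.labels == j)[0]
        if len(members) < 2:
            continue
        agree = sum(
            1
            for a in members
            for b in members
            if a != b and by_train[a] == by_train[b]
        )
        worst = min(worst, agree / (len(members) * (len(members) - 1)))
    return worst


class TestPredictionStrength:
    def test_k1_strength_is_exactly_one(self, rng):
        x = rng.normal(size=(40, 2))
        curve = prediction_strength(x, k_max=1, n_splits=3, seed=0)
        assert curve.ps_mean[0] == 1.0 and curve.ps_sd[0] == 0.0

    def test_two_separated_blobs_select_two(self, rng):
        x = np.vstack([rng.normal(0, 0.5, (100, 2)), rng.normal(20, 0.5, (100, 2))])
        curve = prediction_strength(x, k_max=4, seed=3)
        assert curve.ps_mean[1] > 0.95
        assert curve.ps_mean[2] < curve.ps_mean[1]
        assert curve.selected_k == 2
        assert ((curve.ps_mean >= 0) & (curve.ps_mean <= 1)).all()

    def test_matches_brute_force_pair_counting_on_one_split(self, rng):
        from engagetraj.clustering import _split_strength

        x = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(4, 1, (30, 2))])
        perm = np.random.default_rng(7).permutation(60)
        train, test = perm[:30], perm[30:]
        fast = _split_strength(x, train, test, 2, 11, 12)
        slow = brute_force_split_strength(x, train, test, 2, 11, 12)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_k_max_beyond_half_n_rejected(self, rng):
        with pytest.raises(ValueError):
            prediction_strength(rng.normal(size=(10, 1)), k_max=6, seed=0)


class TestRelabelBySize:
    def test_descending_size_order(self):
        points = np.concatenate(
            [np.full(10, 0.0), np.full(50, 10.0), np.full(20, 20.0)]
        )
        result = relabel_by_size(pam(points, 3))
        sizes = result.cluster_sizes()
        assert sizes.tolist() == sorted(sizes, reverse=True)
        assert result.labels[15] == 1  # member of the 50-point cluster
        assert result.labels[0] == 3  # member of the 10-point cluster
        # relabeling preserves the partition and cost
        assert result.total_cost == pam(points, 3).total_cost

    def test_equal_sizes_tie_broken_by_medoid_index(self):
        points = np.array([0.0, 0.1, 10.0, 10.1])
        result = relabel_by_size(pam(points, 2))
        assert result.medoid_indices.tolist() == sorted(result.medoid_indices)

    def test_single_cluster_unchanged(self):
        result = pam(np.array([0.0, 1.0, 2.0]), 1)
        relabeled = relabel_by_size(result)
        assert np.array_equal(relabeled.labels, result.labels)
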