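import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics.pairwise import nan_euclidean_distances

from fcki import find_knn, knni_estimate, pairwise_distance, select_best_k
from fcki.exceptions import (
    ColumnAllMissingError,
    NoComparableDonorsError,
    PoolTooSmallError,
    ShapeError,
    SpecError,
)

nan = float("nan")


class FixedChoiceRng:
    """Duck-typed generator whose ``choice`` always returns a fixed value."""

    def __init__(self, value):
        self.value = value

    def choice(self, options):
        assert self.value in np.asarray(options)
        return self.value


class TestPairwiseDistance:
    def test_complete_records_classic_euclidean(self):
        assert pairwise_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_partial_distance_rescaled(self):
        # one co-observed column of two: sqrt(2/1 * 9)
        assert pairwise_distance([0, nan], [3, 4]) == pytest.approx(math.sqrt(18))

    def test_no_co_observed_is_infinite(self):
        assert pairwise_distance([nan, nan], [3, 4]) == math.inf

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            pairwise_distance([1, 2], [1, 2, 3])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_sklearn_agreement(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 5))
        holes = rng.random((2, 5)) < 0.3
        a[holes[0]], b[holes[1]] = nan, nan
        d_ab, d_ba = pairwise_distance(a, b), pairwise_distance(b, a)
        assert d_ab == d_ba
        ref = nan_euclidean_distances(a[None, :], b[None, :])[0, 0]
        if np.isnan(ref):
            assert math.isinf(d_ab)
        else:
            assert d_ab == pytest.approx(ref, abs=1e-12)


class TestFindKnn:
    def test_ranks_by_distance(self):
        pool = np.array([[0, 1], [3, 4], [0, 0.5]], dtype=float)
        res = find_knn([0, 0], pool, k=2)
        assert list(res.indices) == [2, 0]
        assert list(res.distances) == pytest.approx([0.5, 1.0])

    def test_k_equals_pool_size_returns_all_sorted(self):
        pool = np.array([[2.0, 0], [1.0, 0], [3.0, 0]])
        res = find_knn([0.0, 0.0], pool, k=3)
        assert list(res.indices) == [1, 0, 2]

    def test_tie_break_lower_position_and_prefix_property(self, rng):
        pool = rng.normal(size=(9, 3))
        pool[4] = pool[1]  # exact duplicate: tie in distance
        target = rng.normal(size=3)
        for k in range(1, 9):
            a = find_knn(target, pool, k)
            b = find_knn(target, pool, k + 1)
            assert list(a.indices) == list(b.indices[:k])
        full = find_knn(target, pool, 9)
        i1, i4 = list(full.indices).index(1), list(full.indices).index(4)
        assert i1 < i4

    def test_k_out_of_range_and_no_donors(self):
        pool = np.array([[1.0, 2.0]])
        with pytest.raises(SpecError):
            find_knn([0.0, 0.0], pool, k=2)
        with pytest.raises(NoComparableDonorsError):
            find_knn([nan, nan], pool, k=1)

    def test_brute_force_oracle_on_incomplete_pools(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pool = rng.normal(size=(10, 4))
            pool[rng.random((10, 4)) < 0.25] = nan
            target = rng.normal(size=4)
            target[rng.random(4) < 0.25] = nan
            if np.isnan(target).all():
                continue
            dists = [pairwise_distance(target, row) for row in pool]
            if all(math.isinf(d) for d in dists):
                continue
            order = sorted(range(10), key=lambda i: (dists[i], i))
            k = int(rng.integers(1, 11))
            res = find_knn(target, pool, k)
            assert list(res.indices) == order[:k]


class TestKnniEstimate:
    def test_mean_of_observed(self):
        assert knni_estimate([[1], [2], [3]], 0) == pytest.approx(2.0)
        assert knni_estimate([[1], [nan], [3]], 0) == pytest.approx(2.0)

    def test_fallback_to_pool_mean(self):
        assert knni_estimate([[nan], [nan]], 0, pool_column_mean=5.0) == 5.0
        with pytest.raises(ColumnAllMissingError):
            knni_estimate([[nan], [nan]], 0)


class TestSelectBestK:
    def test_hand_worked_error_curve(self):
        # donors sorted by distance carry probe values (1, 3, 2, 5); AV = 2
        pool = np.array(
            [
                [1.0, 1.0],
                [2.0, 3.0],
                [3.0, 2.0],
                [4.0, 5.0],
                [0.0, 2.0],  # recipient, AV = 2 at probe column 1
            ]
        )
        sel = select_best_k(pool, target_index=4, rng=FixedChoiceRng(1))
        assert sel.probe_attr == 1 and sel.actual_value == 2.0
        assert sel.error_curve == pytest.approx({2: 0.0, 3: 0.0, 4: 0.75})
        assert sel.best_k == 2  # smallest k on the 0.0 tie

    def test_identical_estimates_tie_to_smallest_k(self):
        pool = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0], [0.0, 7.0]])
        sel = select_best_k(pool, target_index=3, rng=FixedChoiceRng(1))
        assert sel.best_k == 2

    def test_pool_too_small(self):
        with pytest.raises(PoolTooSmallError):
            select_best_k(np.ones((2, 2)), 1, rng=np.random.default_rng(0))

    def test_curve_has_np_minus_2_entries_and_is_reproducible(self, rng):
        pool = rng.normal(size=(8, 3))
        a = select_best_k(pool, 0, rng=np.random.default_rng(5))
        b = select_best_k(pool, 0, rng=np.random.default_rng(5))
        assert len(a.error_curve) == 6
        assert a.best_k == b.best_k and a.probe_attr == b.probe_attr

    def test_exhaustive_oracle_on_random_pools(self):
        """Arg-min k agrees with a full per-k recomputation on 200 pools."""
        checked = 0
        seed = 0
        while checked < 200:
            seed += 1
            rng = np.random.default_rng(seed)
            n_p, m = int(rng.integers(4, 13)), int(rng.integers(2, 7))
            pool = rng.normal(size=(n_p, m))
            pool[rng.random((n_p, m)) < 0.2] = nan
            ti = int(rng.integers(n_p))
            if np.isnan(pool[ti]).all():
                continue
            try:
                sel = select_best_k(pool, ti, rng=np.random.default_rng(seed + 10_000))
            except (NoComparableDonorsError, ColumnAllMissingError):
                continue
            z, av = sel.probe_attr, sel.actual_value
            query = pool[ti].copy()
            if (~np.isnan(query)).sum() > 1:
                query[z] = nan
            donors = [i for i in range(n_p) if i != ti]
            dist = [pairwise_distance(query, pool[i]) for i in donors]
            order = [donors[i] for i in sorted(range(len(donors)), key=lambda i: (dist[i], i))]
            pooled = [pool[i, z] for i in order if not math.isnan(pool[i, z])]
            curve = {}
            for k in range(2, n_p):
                head = [pool[i, z] for i in order[:k] if not math.isnan(pool[i, z])]
                est = sum(head) / len(head) if head else sum(pooled) / len(pooled)
                curve[k] = abs(av - est)
            best = min(curve, key=lambda k: (curve[k], k))
            assert sel.best_k == best
            assert sel.error_curve == pytest.approx(curve)
            checked += 1
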