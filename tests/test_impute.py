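import numpy as np
import pytest

from fcki import (
    FCKIImputer,
    KIImputer,
    NumericDataset,
    fcki_impute,
    ki_impute,
    knni_estimate,
    knni_impute_global,
    mean_impute,
    pairwise_distance,
)
from fcki.exceptions import ColumnAllMissingError, SpecError

from .conftest import dataset, random_incomplete

nan = float("nan")


class TestKi:
    def test_complete_dataset_identity(self, rng):
        x = rng.normal(size=(6, 3))
        res = ki_impute(NumericDataset(x), seed=0)
        np.testing.assert_array_equal(res.imputed.values, x)
        assert res.per_record_log == []

    def test_collinear_recovery(self):
        x = np.arange(1.0, 7.0)
        d = np.column_stack([x, 2 * x])
        d[2, 1] = nan
        res = ki_impute(dataset(d), seed=0)
        assert res.imputed.values[2, 1] == pytest.approx(6.0, abs=0.1)
        (entry,) = res.per_record_log
        assert entry.best_k >= 2 and entry.fallback_used is None

    def test_empty_pool_falls_back_to_column_mean(self):
        # only one other row observes column 0, so N_p = 2 < 3
        d = dataset([[nan, 1.0], [nan, 2.0], [nan, 4.0], [6.0, 5.0]])
        res = ki_impute(d, seed=1)
        assert not np.isnan(res.imputed.values).any()
        # the first incomplete record has no usable pool and takes the mean;
        # later records may already lean on its imputed (sequential) value
        assert res.per_record_log[0].fallback_used == "column_mean"
        np.testing.assert_allclose(res.imputed.values[:3, 0], 6.0)

    def test_record_missing_all_values_is_imputed_by_fallback(self, rng):
        x = rng.normal(size=(8, 3))
        x[2] = nan
        res = ki_impute(NumericDataset(x), seed=2)
        assert not np.isnan(res.imputed.values).any()
        entry = [e for e in res.per_record_log if e.record_index == 2][0]
        assert entry.fallback_used == "column_mean"

    def test_observed_cells_bit_identical_and_deterministic(self, rng):
        x = random_incomplete(rng, 15, 4)
        a = ki_impute(NumericDataset(x), seed=5).imputed.values
        b = ki_impute(NumericDataset(x), seed=5).imputed.values
        obs = ~np.isnan(x)
        np.testing.assert_array_equal(a[obs], x[obs])
        np.testing.assert_array_equal(a, b)
        assert not np.isnan(a).any()

    def test_records_processed_in_ascending_order(self, rng):
        x = random_incomplete(rng, 12, 4)
        res = ki_impute(NumericDataset(x), seed=3)
        idx = [e.record_index for e in res.per_record_log]
        assert idx == sorted(idx)

    def test_column_all_missing_rejected(self):
        with pytest.raises(ColumnAllMissingError):
            ki_impute(dataset([[nan, 1], [nan, 2]]), seed=0)


class TestFcki:
    def test_fixed_c1_reduces_to_ki_bit_identically(self, rng):
        for _ in range(5):
            x = random_incomplete(rng, 14, 4)
            seed = int(rng.integers(2**31))
            a = ki_impute(NumericDataset(x), seed=seed).imputed.values
            b = fcki_impute(NumericDataset(x), c=1, seed=seed).imputed.values
            np.testing.assert_array_equal(a, b)

    def test_small_dataset_without_fixed_c_bypasses_clustering(self, rng):
        x = random_incomplete(rng, 10, 3)
        seed = 77
        a = fcki_impute(NumericDataset(x), seed=seed).imputed.values
        b = ki_impute(NumericDataset(x), seed=seed).imputed.values
        np.testing.assert_array_equal(a, b)

    def test_per_cluster_slopes_respected(self):
        xa = np.linspace(1, 2, 8)
        xb = np.linspace(30, 31, 8)
        d = np.vstack(
            [np.column_stack([xa, 2 * xa]), np.column_stack([xb, -3 * xb])]
        )
        d[3, 1] = nan
        d[11, 1] = nan
        res = fcki_impute(dataset(d), c=2, seed=1)
        assert res.imputed.values[3, 1] == pytest.approx(2 * xa[3], abs=0.1)
        assert res.imputed.values[11, 1] == pytest.approx(-3 * xb[3], abs=0.1)

    def test_routing_uses_highest_membership_cluster(self):
        xa = np.linspace(1, 2, 8)
        xb = np.linspace(30, 31, 8)
        d = np.vstack(
            [np.column_stack([xa, 2 * xa]), np.column_stack([xb, -3 * xb])]
        )
        d[3, 1] = nan
        est = FCKIImputer(n_clusters=2, random_state=1)
        est.fit(d)
        out = est.transform(d)
        (entry,) = est.per_record_log_
        assert entry.cluster_id == est.labels_[3]
        assert not np.isnan(out).any()

    def test_cluster_and_seed_recorded_in_log(self, rng):
        x = random_incomplete(rng, 40, 4)
        res = fcki_impute(NumericDataset(x), c=2, seed=9)
        assert all(e.cluster_id in (0, 1) for e in res.per_record_log)
        assert res.config_echo["random_state"] == 9


class TestMeanImpute:
    def test_column_mean_fills(self):
        d = dataset([[1.0], [2.0], [nan], [3.0]])
        res = mean_impute(d)
        assert res.imputed.values[2, 0] == pytest.approx(2.0)

    def test_identity_on_complete(self, rng):
        x = rng.normal(size=(4, 3))
        np.testing.assert_allclose(mean_impute(NumericDataset(x)).imputed.values, x)

    def test_all_missing_cells_in_column_get_same_value(self, rng):
        x = rng.normal(size=(8, 2))
        x[[1, 4, 6], 0] = nan
        out = mean_impute(NumericDataset(x)).imputed.values
        assert len(set(out[[1, 4, 6], 0])) == 1


class TestGlobalKnni:
    def test_mean_of_neighbour_values(self):
        d = dataset([[0.0, nan], [0.0, 1.0], [0.1, 3.0], [50.0, 9.0]])
        res = knni_impute_global(d, k=2)
        assert res.imputed.values[0, 1] == pytest.approx(2.0)

    def test_k_all_donors_equals_column_mean_excluding_self(self, rng):
        x = rng.normal(size=(7, 3))
        x[0, 2] = nan
        res = knni_impute_global(NumericDataset(x), k=6)
        assert res.imputed.values[0, 2] == pytest.approx(np.nanmean(x[1:, 2]))

    def test_k_out_of_range(self, rng):
        x = rng.normal(size=(4, 2))
        x[0, 0] = nan
        with pytest.raises(SpecError):
            knni_impute_global(NumericDataset(x), k=4)
        with pytest.raises(SpecError):
            knni_impute_global(NumericDataset(x), k=0)

    def test_brute_force_oracle_on_random_datasets(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = random_incomplete(rng, 12, 4, frac=0.2)
            k = int(rng.integers(1, 12))
            res = knni_impute_global(NumericDataset(x), k=k).imputed.values
            col_means = np.nanmean(x, axis=0)
            for i in range(12):
                mis = np.flatnonzero(np.isnan(x[i]))
                if mis.size == 0:
                    continue
                dists = [
                    (pairwise_distance(x[i], x[r]), r) for r in range(12) if r != i
                ]
                order = [r for _, r in sorted(dists, key=lambda t: (t[0], t[1]))]
                donors = x[order[:k]]
                for j in mis:
                    expect = knni_estimate(donors, int(j), pool_column_mean=col_means[j])
                    assert res[i, j] == pytest.approx(expect)


class TestSklearnCompat:
    def test_get_set_params_round_trip(self):
        est = KIImputer(random_state=3)
        params = est.get_params()
        clone = KIImputer(**params)
        assert clone.get_params() == params

    def test_pipeline_composition(self, rng):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        x = random_incomplete(rng, 20, 3)
        pipe = Pipeline([("impute", KIImputer(random_state=0)), ("scale", StandardScaler())])
        out = pipe.fit_transform(x)
        assert out.shape == x.shape and not np.isnan(out).any()
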