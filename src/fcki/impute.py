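"""Hybrid hot-deck imputers: KI, its fuzzy-cluster-routed variant FCKI, and
the column-mean and global kNNI baselines.

KI processes incomplete records one at a time in ascending row order. For a
recipient R_i it builds the donor pool P — every other record observed on
all of R_i's missing attributes (donors may be missing elsewhere; no fully
complete record is required anywhere) — adds R_i to P, picks k by the
self-probe search, takes the k nearest donors, and hands the small subset
S = d_k ∪ {R_i} to the round-robin regression imputer. Only R_i's cells are
accepted; the completed record immediately rejoins the working dataset, so
later records may draw on earlier imputations.

FCKI first soft-clusters the (incomplete) dataset with fuzzy c-means,
hard-assigns each record to its highest-membership cluster, and runs the KI
procedure within each cluster; a record whose within-cluster pool is too
small is retried against the whole dataset. With a single cluster FCKI
reduces bit-exactly to KI under the same seed.

When no usable donor exists at all (pool under 3 records and no
whole-dataset retry, a recipient with every value missing, or a probe
nobody observes) the record falls back to observed column means; every
fallback is recorded in the per-record log.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import SimpleImputer

from .dataset import NumericDataset, as_dataset
from .exceptions import (
    ColumnAllMissingError,
    EmptyInputError,
    NoComparableDonorsError,
    PoolTooSmallError,
    SpecError,
)
from .fuzzy import FuzzyCMeans, default_c_max, elbow_select_c
from .iterative import IterConfig, _round_robin
from .neighbors import find_knn, knni_estimate, select_best_k


@dataclass
class RecordLog:
    """One imputed record's provenance inside a KI/FCKI run."""

    record_index: int
    best_k: int | None = None
    pool_size: int | None = None
    cluster_id: int | None = None
    fallback_used: str | None = None


@dataclass
class ImputationResult:
    """A completed dataset plus the per-record log and the effective config."""

    imputed: NumericDataset
    per_record_log: list[RecordLog] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)


def _validate_imputable(X: np.ndarray) -> None:
    if X.size == 0:
        raise EmptyInputError("cannot impute an empty dataset")
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        raise ColumnAllMissingError(
            f"column {int(np.flatnonzero(all_missing)[0])} has no observed value"
        )


def _impute_record(
    X: np.ndarray,
    i: int,
    candidate_rows: np.ndarray,
    rng: np.random.Generator,
    config: IterConfig,
) -> tuple[np.ndarray, int, int]:
    """One KI step for record ``i`` drawing donors from ``candidate_rows``.

    Returns (values for the missing attributes, best_k, pool size N_p);
    raises the donor-pool errors for the caller's fallback ladder.
    """
    a_mis = np.flatnonzero(np.isnan(X[i]))
    pool_rows = np.array(
        [r for r in candidate_rows if r != i and not np.isnan(X[r, a_mis]).any()],
        dtype=int,
    )
    pool = np.vstack([X[pool_rows], X[i][None, :]]) if pool_rows.size else X[i][None, :]
    selection = select_best_k(pool, target_index=pool.shape[0] - 1, rng=rng)
    # final donor search with the probe restored: the full record ranks P
    nn = find_knn(X[i], pool[:-1], selection.best_k)
    donors = pool_rows[nn.indices]
    subset = np.vstack([X[donors], X[i][None, :]])
    filled, _, _ = _round_robin(subset, config)
    return filled[-1, a_mis], selection.best_k, pool.shape[0]


def _ki_pass(
    X: np.ndarray,
    rows: np.ndarray,
    rng: np.random.Generator,
    config: IterConfig,
    log: list[RecordLog],
    cluster_id: int | None = None,
    retry_rows: np.ndarray | None = None,
) -> None:
    """Impute every incomplete record among ``rows`` in ascending order, in place."""
    donor_errors = (PoolTooSmallError, NoComparableDonorsError, ColumnAllMissingError, SpecError)
    for i in np.sort(rows):
        a_mis = np.flatnonzero(np.isnan(X[i]))
        if a_mis.size == 0:
            continue
        entry = RecordLog(record_index=int(i), cluster_id=cluster_id)
        try:
            values, entry.best_k, entry.pool_size = _impute_record(X, i, rows, rng, config)
        except donor_errors:
            values = None
            if retry_rows is not None:
                try:
                    values, entry.best_k, entry.pool_size = _impute_record(
                        X, i, retry_rows, rng, config
                    )
                    entry.fallback_used = "whole_dataset"
                except donor_errors:
                    values = None
            if values is None:
                col_means = np.nanmean(X[:, a_mis], axis=0)
                if np.isnan(col_means).any():
                    raise ColumnAllMissingError(
                        f"record {i}: a missing attribute has no observed value anywhere"
                    )
                values = col_means
                entry.fallback_used = "column_mean"
        X[i, a_mis] = values
        log.append(entry)


class KIImputer(BaseEstimator, TransformerMixin):
    """Automatic-k nearest-neighbour donor selection + round-robin regression.

    Transductive: ``transform(X)`` returns a completed copy of ``X``.
    ``per_record_log_`` afterwards lists, per imputed record, the chosen k,
    the pool size and any fallback taken.
    """

    def __init__(
        self,
        max_rounds: int = 10,
        tol: float = 1e-3,
        ridge_lambda: float | None = None,
        clip_to_observed_range: bool = False,
        random_state: int | None = None,
    ):
        self.max_rounds = max_rounds
        self.tol = tol
        self.ridge_lambda = ridge_lambda
        self.clip_to_observed_range = clip_to_observed_range
        self.random_state = random_state

    def _iter_config(self) -> IterConfig:
        return IterConfig(
            max_rounds=self.max_rounds,
            tol=self.tol,
            ridge_lambda=self.ridge_lambda,
            clip_to_observed_range=self.clip_to_observed_range,
        )

    def fit(self, X, y=None):
        X = np.asarray(as_dataset(X).values, dtype=float)
        _validate_imputable(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(as_dataset(X).values, dtype=float).copy()
        _validate_imputable(X)
        rng = np.random.default_rng(self.random_state)
        log: list[RecordLog] = []
        _ki_pass(X, np.arange(X.shape[0]), rng, self._iter_config(), log)
        self.per_record_log_ = log
        return X


class FCKIImputer(BaseEstimator, TransformerMixin):
    """Fuzzy-c-means cluster routing around the KI procedure.

    The cluster count comes from ``n_clusters`` when given, otherwise from
    an elbow sweep over [c_min, c_max] (default c_max = min(10,
    floor(sqrt(N/2)))). ``n_clusters=1`` — or a dataset too small for the
    sweep — bypasses clustering entirely and reduces to ``KIImputer``
    bit-for-bit under the same seed.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        c_min: int = 2,
        c_max: int | None = None,
        m_prime: float = 2.0,
        fcm_tol: float = 1e-4,
        fcm_max_iter: int = 100,
        max_rounds: int = 10,
        tol: float = 1e-3,
        ridge_lambda: float | None = None,
        clip_to_observed_range: bool = False,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.c_min = c_min
        self.c_max = c_max
        self.m_prime = m_prime
        self.fcm_tol = fcm_tol
        self.fcm_max_iter = fcm_max_iter
        self.max_rounds = max_rounds
        self.tol = tol
        self.ridge_lambda = ridge_lambda
        self.clip_to_observed_range = clip_to_observed_range
        self.random_state = random_state

    def _iter_config(self) -> IterConfig:
        return IterConfig(
            max_rounds=self.max_rounds,
            tol=self.tol,
            ridge_lambda=self.ridge_lambda,
            clip_to_observed_range=self.clip_to_observed_range,
        )

    def _fcm_seed(self) -> int | None:
        if self.random_state is None:
            return None
        return int(np.random.SeedSequence(self.random_state).generate_state(1)[0] % 2**31)

    def fit(self, X, y=None):
        X = np.asarray(as_dataset(X).values, dtype=float)
        _validate_imputable(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(as_dataset(X).values, dtype=float).copy()
        _validate_imputable(X)
        n = X.shape[0]

        c = self.n_clusters
        if c is None:
            c_max = self.c_max if self.c_max is not None else default_c_max(n)
            if c_max - self.c_min < 2 or c_max > n:
                c = 1  # dataset too small for an elbow sweep: single cluster
            else:
                c = elbow_select_c(
                    X,
                    c_min=self.c_min,
                    c_max=c_max,
                    m_prime=self.m_prime,
                    tol=self.fcm_tol,
                    max_iter=self.fcm_max_iter,
                    seed=self._fcm_seed(),
                )
        c = int(c)
        if c < 1:
            raise SpecError(f"n_clusters must be >= 1, got {c}")

        rng = np.random.default_rng(self.random_state)
        log: list[RecordLog] = []
        all_rows = np.arange(n)
        if c == 1:
            self.labels_ = np.zeros(n, dtype=int)
            self.n_clusters_ = 1
            _ki_pass(X, all_rows, rng, self._iter_config(), log)
        else:
            fcm = FuzzyCMeans(
                n_clusters=c,
                m=self.m_prime,
                tol=self.fcm_tol,
                max_iter=self.fcm_max_iter,
                random_state=self._fcm_seed(),
            ).fit(X)
            self.labels_ = fcm.labels_
            self.membership_ = fcm.membership_
            self.n_clusters_ = c
            for k in range(c):
                cluster_rows = np.flatnonzero(fcm.labels_ == k)
                if cluster_rows.size == 0:
                    continue
                _ki_pass(
                    X,
                    cluster_rows,
                    rng,
                    self._iter_config(),
                    log,
                    cluster_id=k,
                    retry_rows=all_rows,
                )
        self.per_record_log_ = log
        return X


class MeanImputer(BaseEstimator, TransformerMixin):
    """Observed column-mean imputation (the classical worst-case baseline)."""

    def fit(self, X, y=None):
        X = np.asarray(as_dataset(X).values, dtype=float)
        _validate_imputable(X)
        self.n_features_in_ = X.shape[1]
        self._imputer = SimpleImputer(strategy="mean", keep_empty_features=False)
        self._imputer.fit(X)
        return self

    def transform(self, X):
        X = np.asarray(as_dataset(X).values, dtype=float)
        _validate_imputable(X)
        return self._imputer.transform(X)


class GlobalKNNImputer(BaseEstimator, TransformerMixin):
    """kNN imputation against the whole dataset with a fixed k.

    Each incomplete record's k nearest records (partial distance, every
    other row a candidate) supply each missing cell as the observed mean of
    that attribute over the neighbours, falling back to the overall
    observed column mean when no neighbour observes it. Donor values are
    always the original ones — no sequential update.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None):
        X = np.asarray(as_dataset(X).values, dtype=float)
        _validate_imputable(X)
        if not 1 <= int(self.n_neighbors) < X.shape[0]:
            raise SpecError(f"n_neighbors must lie in [1, {X.shape[0] - 1}], got {self.n_neighbors}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(as_dataset(X).values, dtype=float)
        _validate_imputable(X)
        k = int(self.n_neighbors)
        if not 1 <= k < X.shape[0]:
            raise SpecError(f"n_neighbors must lie in [1, {X.shape[0] - 1}], got {k}")
        out = X.copy()
        col_means = np.nanmean(X, axis=0)
        for i in np.flatnonzero(np.isnan(X).any(axis=1)):
            a_mis = np.flatnonzero(np.isnan(X[i]))
            try:
                nn = find_knn(X[i], X, k, exclude_index=i)
                donors = X[nn.indices]
                for j in a_mis:
                    out[i, j] = knni_estimate(donors, int(j), pool_column_mean=col_means[j])
            except NoComparableDonorsError:
                out[i, a_mis] = col_means[a_mis]
        return out


def _result(est, data, values: np.ndarray, **extra) -> ImputationResult:
    imputed = NumericDataset(values, list(data.row_ids), list(data.col_names))
    echo = dict(est.get_params(), **extra)
    log = list(getattr(est, "per_record_log_", []))
    return ImputationResult(imputed=imputed, per_record_log=log, config_echo=echo)


def ki_impute(data, config: IterConfig | None = None, seed: int | None = None) -> ImputationResult:
    """Impute every missing cell of ``data`` with the KI procedure."""
    data = as_dataset(data)
    cfg = config or IterConfig()
    est = KIImputer(random_state=seed, **asdict(cfg))
    return _result(est, data, est.fit(data).transform(data))


def fcki_impute(
    data,
    config: IterConfig | None = None,
    c: int | None = None,
    m_prime: float = 2.0,
    seed: int | None = None,
) -> ImputationResult:
    """Impute ``data`` with fuzzy-cluster-routed KI (elbow-chosen c unless fixed)."""
    data = as_dataset(data)
    cfg = config or IterConfig()
    est = FCKIImputer(n_clusters=c, m_prime=m_prime, random_state=seed, **asdict(cfg))
    return _result(est, data, est.fit(data).transform(data))


def mean_impute(data) -> ImputationResult:
    """Column observed-mean imputation."""
    data = as_dataset(data)
    est = MeanImputer()
    return _result(est, data, est.fit(data).transform(data))


def knni_impute_global(data, k: int) -> ImputationResult:
    """Whole-dataset kNN imputation with a fixed neighbour count."""
    data = as_dataset(data)
    est = GlobalKNNImputer(n_neighbors=k)
    return _result(est, data, est.fit(data).transform(data))
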