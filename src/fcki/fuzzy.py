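"""Fuzzy c-means on possibly incomplete data, with elbow selection of c.

The fit minimises the fuzzified within-cluster objective
``J = Σ_i Σ_k δ_ik^{m'} d²(R_i, c_k)`` by alternating the closed-form
membership and centroid updates. Missing cells enter through the
partial-distance strategy: squared distances are taken over a record's
observed attributes and rescaled by M/m_obs, and centroid components
average only the records that observe them (weighted by δ^{m'}). On
complete data this reduces exactly to standard FCM.

The fuzzifier m' > 1 sets how much clusters may overlap (m' → 1 approaches
hard k-means, large m' washes memberships out); 2.0 is the conventional
default. Membership rows are initialised from a flat Dirichlet draw, which
is reproducible under a seed and cannot place two centroids on the same
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .dataset import as_dataset
from .exceptions import ColumnAllMissingError, SpecError


@dataclass
class FCMModel:
    """A converged fuzzy c-means fit."""

    centroids: np.ndarray
    membership: np.ndarray
    fuzzifier: float
    objective_trace: list[float] = field(default_factory=list)
    seed: int | None = None
    n_iter: int = 0


@dataclass
class ClusterPartition:
    """Hard assignment derived from a membership matrix."""

    labels: np.ndarray
    clusters: list[list[int]]


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Scikit-learn style fuzzy c-means clusterer tolerant of NaN cells.

    Parameters
    ----------
    n_clusters : int
        Number of clusters c, in [2, N].
    m : float
        Fuzzifier m' > 1.
    tol : float
        Convergence threshold on the largest membership change.
    max_iter : int
        Iteration cap.
    random_state : int, optional
        Seed of the Dirichlet membership initialisation.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (c, M)
    membership_ : ndarray of shape (N, c); rows sum to 1.
    labels_ : hard assignment by highest membership, ties to the lowest
        cluster index.
    objective_trace_ : per-iteration objective values (non-increasing).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        m: float = 2.0,
        tol: float = 1e-4,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(as_dataset(X).values, dtype=float)
        n, mm = X.shape
        c = int(self.n_clusters)
        if not 2 <= c <= n:
            raise SpecError(f"n_clusters must lie in [2, {n}], got {c}")
        if not self.m > 1:
            raise SpecError(f"fuzzifier must exceed 1, got {self.m}")
        all_missing = np.isnan(X).all(axis=0)
        if all_missing.any():
            raise ColumnAllMissingError(
                f"column {int(np.flatnonzero(all_missing)[0])} has no observed value"
            )

        obs = ~np.isnan(X)
        x0 = np.where(obs, X, 0.0)
        m_obs = obs.sum(axis=1)
        # each record's weight in the centroid update carries the same
        # M/m_obs rescaling as its distances, so both updates minimise one
        # objective and the trace stays monotone
        row_scale = np.where(m_obs > 0, mm / np.maximum(m_obs, 1), 0.0)
        col_means = np.nanmean(X, axis=0)
        rng = np.random.default_rng(self.random_state)
        membership = rng.dirichlet(np.ones(c), size=n)
        exponent = 2.0 / (self.m - 1.0)

        trace: list[float] = []
        n_iter = 0
        for n_iter in range(1, int(self.max_iter) + 1):
            w = membership**self.m * row_scale[:, None]
            denom = w.T @ obs  # (c, M) total weight observing each component
            numer = w.T @ x0
            with np.errstate(invalid="ignore", divide="ignore"):
                centroids = numer / denom
            bad = denom <= 0
            if bad.any():  # no weight observes the component: fall back to the column mean
                centroids[bad] = np.broadcast_to(col_means, centroids.shape)[bad]

            d2 = _sq_partial_distances(x0, obs, m_obs, centroids)
            new_membership = _membership_from_d2(d2, exponent)
            trace.append(float(np.sum(new_membership**self.m * d2)))

            delta = np.abs(new_membership - membership).max()
            membership = new_membership
            if delta < self.tol:
                break

        self.cluster_centers_ = centroids
        self.membership_ = membership
        self.objective_trace_ = trace
        self.n_iter_ = n_iter
        self.labels_ = np.argmax(membership, axis=1)
        self.objective_ = trace[-1]
        return self

    def predict(self, X):
        """Hard-assign new records to the nearest fitted structure."""
        X = np.asarray(as_dataset(X).values, dtype=float)
        obs = ~np.isnan(X)
        d2 = _sq_partial_distances(np.where(obs, X, 0.0), obs, obs.sum(axis=1), self.cluster_centers_)
        exponent = 2.0 / (self.m - 1.0)
        return np.argmax(_membership_from_d2(d2, exponent), axis=1)


def _sq_partial_distances(x0, obs, m_obs, centroids) -> np.ndarray:
    """Squared M/m_obs-rescaled distances from each record to each centroid."""
    n, mm = x0.shape
    d2 = np.empty((n, centroids.shape[0]))
    for k, ck in enumerate(centroids):
        diff = np.where(obs, x0 - ck[None, :], 0.0)
        d2[:, k] = (diff**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = mm / m_obs[:, None] * d2
    d2[m_obs == 0] = np.inf  # fully-missing record: no distance is defined
    return d2


def _membership_from_d2(d2: np.ndarray, exponent: float) -> np.ndarray:
    """Closed-form membership update δ_ik = 1 / Σ_j (d_ik/d_ij)^{2/(m'−1)}."""
    n, c = d2.shape
    membership = np.empty_like(d2)
    zero_rows = (d2 == 0).any(axis=1)
    inf_rows = np.isinf(d2).all(axis=1)
    ordinary = ~zero_rows & ~inf_rows
    with np.errstate(divide="ignore", over="ignore"):
        # d^{-2/(m'-1)} written on the squared distances: d2^{-exponent/2}
        inv = d2[ordinary] ** (-exponent / 2.0)
    membership[ordinary] = inv / inv.sum(axis=1, keepdims=True)
    for i in np.flatnonzero(zero_rows):  # coincident with >=1 centroid: all mass there
        hits = d2[i] == 0
        membership[i] = hits / hits.sum()
    membership[inf_rows] = 1.0 / c  # no information: uniform membership
    return membership


def fcm_fit(
    data,
    c: int,
    m_prime: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int | None = None,
) -> FCMModel:
    """Fit fuzzy c-means and return the full model record."""
    est = FuzzyCMeans(n_clusters=c, m=m_prime, tol=tol, max_iter=max_iter, random_state=seed).fit(data)
    return FCMModel(
        centroids=est.cluster_centers_,
        membership=est.membership_,
        fuzzifier=float(m_prime),
        objective_trace=est.objective_trace_,
        seed=seed,
        n_iter=est.n_iter_,
    )


def hard_assign(model: FCMModel) -> ClusterPartition:
    """Label each record by its highest-membership cluster (ties: lowest index)."""
    labels = np.argmax(model.membership, axis=1)
    c = model.membership.shape[1]
    clusters = [list(np.flatnonzero(labels == k)) for k in range(c)]
    return ClusterPartition(labels=labels, clusters=clusters)


def default_c_max(n: int) -> int:
    """Default upper end of the elbow sweep: min(10, floor(sqrt(N/2)))."""
    return int(min(10, np.floor(np.sqrt(n / 2.0))))


def elbow_select_c(
    data,
    c_min: int = 2,
    c_max: int | None = None,
    m_prime: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int | None = None,
) -> int:
    """Pick the cluster count at the elbow of the objective-vs-c curve.

    Fits FCM for every c in [c_min, c_max] and returns the interior c
    maximising the discrete second difference J(c−1) − 2·J(c) + J(c+1); if
    no interior point has a positive second difference (the curve bends
    nowhere) the sweep degenerates to ``c_min``.
    """
    data = as_dataset(data)
    n = data.n_rows
    if c_max is None:
        c_max = default_c_max(n)
    if not (2 <= c_min < c_max <= n) or c_max - c_min < 2:
        raise SpecError(f"elbow sweep needs 2 <= c_min < c_max <= N with span >= 2, got [{c_min}, {c_max}] for N={n}")
    cs = list(range(c_min, c_max + 1))
    fit_seeds = np.random.default_rng(seed).integers(2**31, size=len(cs))
    objectives = [
        fcm_fit(data, c, m_prime=m_prime, tol=tol, max_iter=max_iter, seed=int(s)).objective_trace[-1]
        for c, s in zip(cs, fit_seeds)
    ]
    return elbow_from_curve(cs, objectives)


def elbow_from_curve(cs: list[int], objectives: list[float]) -> int:
    """Second-difference elbow of a (c, J(c)) curve; degenerate → smallest c."""
    best_c, best_dd = cs[0], 0.0
    for idx in range(1, len(cs) - 1):
        dd = objectives[idx - 1] - 2.0 * objectives[idx] + objectives[idx + 1]
        if dd > best_dd:
            best_c, best_dd = cs[idx], dd
    return int(best_c)
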