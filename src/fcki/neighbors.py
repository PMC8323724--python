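"""Missing-aware nearest-neighbour search and automatic k selection.

Distances between incomplete records use the partial-distance convention:
the squared Euclidean distance over co-observed attributes is rescaled by
M/m_obs so records with different observed supports stay comparable, and a
pair with no co-observed attribute is infinitely far apart. On complete
records this reduces exactly to the Euclidean distance.

The automatic k selection is a self-probe: one observed value of the
recipient record is withheld, every candidate k in [2, N_p − 1] is scored by
the absolute error of the k-donor mean estimate of that value, and the
smallest arg-min k wins. The withheld value is also excluded from the
distance during the sweep — otherwise the probe would help pick its own
donors and the score would be circular — except in the degenerate case
where withholding it would leave the recipient with no observed attribute
at all. A single distance sort serves the whole sweep; the per-k estimates
are rolled forward incrementally from the sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ColumnAllMissingError,
    NoComparableDonorsError,
    PoolTooSmallError,
    ShapeError,
    SpecError,
)


@dataclass
class NeighborResult:
    """Donor rows ordered by non-decreasing partial distance.

    ``indices`` are positions within the pool; ties in distance are broken
    by the lower pool position, and infinite-distance rows rank last.
    """

    indices: np.ndarray
    distances: np.ndarray


@dataclass
class KSelection:
    """Record of one automatic-k search.

    ``error_curve`` maps each candidate k to the absolute error of the
    k-donor estimate of the withheld probe value; ``best_k`` is the smallest
    k attaining its minimum. ``donor_order`` preserves the distance-sorted
    pool positions so the chosen neighbourhood can be reused without a
    second search.
    """

    probe_attr: int
    actual_value: float
    error_curve: dict[int, float]
    best_k: int
    donor_order: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def pairwise_distance(a, b) -> float:
    """Partial Euclidean distance between two records of equal length.

    Returns ``sqrt((M / m_obs) · Σ_{j co-observed} (a_j − b_j)²)``, or +inf
    when no attribute is observed in both records.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"record lengths differ: {a.shape[0]} vs {b.shape[0]}")
    both = ~np.isnan(a) & ~np.isnan(b)
    m_obs = int(both.sum())
    if m_obs == 0:
        return float("inf")
    d2 = float(np.sum((a[both] - b[both]) ** 2))
    return float(np.sqrt(a.size / m_obs * d2))


def _distances_to_pool(target: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Vectorised partial distances from one record to every pool row."""
    target = np.asarray(target, dtype=float).ravel()
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2 or pool.shape[1] != target.size:
        raise ShapeError("pool must be 2-D with rows the length of the target record")
    both = ~np.isnan(target)[None, :] & ~np.isnan(pool)
    diff = np.where(both, pool - target[None, :], 0.0)
    m_obs = both.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(target.size / m_obs * (diff**2).sum(axis=1))
    d[m_obs == 0] = np.inf
    return d


def _sorted_donors(target, pool, exclude_index=None):
    d = _distances_to_pool(target, pool)
    idx = np.arange(pool.shape[0])
    if exclude_index is not None:
        keep = idx != exclude_index
        idx, d = idx[keep], d[keep]
    order = np.lexsort((idx, d))  # distance first, then lower pool position
    return idx[order], d[order]


def find_knn(target, pool, k: int, exclude_index: int | None = None) -> NeighborResult:
    """The k pool rows nearest to ``target`` under the partial distance.

    ``exclude_index`` removes the query's own row when it sits in the pool.
    Raises ``SpecError`` if k is out of range and ``NoComparableDonorsError``
    if every candidate is infinitely far from the target.
    """
    pool = np.asarray(pool, dtype=float)
    indices, distances = _sorted_donors(target, pool, exclude_index)
    if not 1 <= k <= indices.size:
        raise SpecError(f"k={k} out of range [1, {indices.size}]")
    if np.isinf(distances).all():
        raise NoComparableDonorsError("no pool row shares an observed attribute with the target")
    return NeighborResult(indices=indices[:k].copy(), distances=distances[:k].copy())


def knni_estimate(neighbors, attr: int, pool_column_mean: float | None = None) -> float:
    """Mean of ``attr`` over the neighbours that observe it.

    Falls back to ``pool_column_mean`` when no neighbour observes the
    attribute; raises ``ColumnAllMissingError`` when the fallback is absent
    or itself undefined.
    """
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if neighbors.shape[0] == 0:
        raise SpecError("neighbour set is empty")
    col = neighbors[:, attr]
    obs = ~np.isnan(col)
    if obs.any():
        return float(col[obs].mean())
    if pool_column_mean is None or np.isnan(pool_column_mean):
        raise ColumnAllMissingError(f"attribute {attr} observed in no neighbour and no fallback given")
    return float(pool_column_mean)


def select_best_k(pool, target_index: int, rng: np.random.Generator) -> KSelection:
    """Automatic k selection by self-probe over a donor pool.

    ``pool`` is the N_p×M donor pool with the recipient record included at
    row ``target_index``. A probe attribute z is drawn uniformly from the
    recipient's observed attributes and its value withheld — from the
    estimate and (unless the recipient observes nothing else) from the
    distance; each k ∈ [2, N_p − 1] is scored by
    |AV − mean_z(k nearest donors)| and the smallest minimising k returned.
    Donors not observing z are skipped in the mean; if none of the first k
    observe it, the donors' overall observed mean of z stands in.

    Raises ``PoolTooSmallError`` for N_p < 3, ``NoComparableDonorsError``
    when the recipient shares no observed attribute with any donor, and
    ``ColumnAllMissingError`` when no donor observes the probe at all.
    """
    pool = np.asarray(pool, dtype=float)
    n_p = pool.shape[0]
    if n_p < 3:
        raise PoolTooSmallError(f"automatic k needs a pool of at least 3 records, got {n_p}")
    target = pool[target_index]
    observed = np.flatnonzero(~np.isnan(target))
    if observed.size == 0:
        raise NoComparableDonorsError("recipient record has no observed attribute to probe")
    z = int(rng.choice(observed))
    av = float(target[z])

    query = target.copy()
    if observed.size > 1:
        query[z] = np.nan  # withhold the probe from the similarity too
    order, dists = _sorted_donors(query, pool, exclude_index=target_index)
    if np.isinf(dists).all():
        raise NoComparableDonorsError("no donor shares an observed attribute with the recipient")

    probe_vals = pool[order, z]
    probe_obs = ~np.isnan(probe_vals)
    if not probe_obs.any():
        raise ColumnAllMissingError(f"probe attribute {z} observed in no donor")
    fallback = float(probe_vals[probe_obs].mean())

    error_curve: dict[int, float] = {}
    running_sum, running_n = 0.0, 0
    for rank in range(n_p - 1):
        if probe_obs[rank]:
            running_sum += float(probe_vals[rank])
            running_n += 1
        k = rank + 1
        if 2 <= k <= n_p - 1:
            est = running_sum / running_n if running_n else fallback
            error_curve[k] = abs(av - est)

    best_k = min(error_curve, key=lambda k: (error_curve[k], k))
    return KSelection(
        probe_attr=z,
        actual_value=av,
        error_curve=error_curve,
        best_k=int(best_k),
        donor_order=order.copy(),
    )
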