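"""Synthetic correlated Gaussian-mixture datasets for tests and benchmarks.

The generator emulates the structure the imputers exploit in real tabular
data: records fall into one or more clusters (local similarity for the
nearest-neighbour step) and features are mutually correlated within a
cluster (the signal the round-robin regression recovers). Each cluster is a
multivariate Gaussian with unit marginal variances and a constant pairwise
feature correlation; cluster centroids sit ``separation`` within-cluster
standard deviations apart along the all-ones direction; iid Gaussian jitter
of scale ``noise_sigma`` is added on top. Rows are shuffled so cluster
membership is not encoded in row order; the generating labels are returned
for recovery tests.

By default each cluster carries its own orientation of the dependence
structure (a seeded ±1 sign pattern over the features, the first cluster
unflipped): the magnitude of every within-cluster pairwise correlation is
the target everywhere, but which pairs co-vary positively differs from
cluster to cluster — the regime cluster-local imputation exists for, where
a donor from the wrong cluster is actively misleading rather than merely
distant. With ``vary_orientation=False`` (or a single cluster) every
cluster shares one structure and the pooled sample keeps the target
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import NumericDataset
from .exceptions import SpecError


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic draw.

    separation is the inter-centroid distance in units of the
    within-cluster standard deviation; correlation is the target pairwise
    feature correlation within a cluster, in [0, 1).
    """

    n: int
    m: int
    n_clusters: int = 1
    separation: float = 0.0
    correlation: float = 0.0
    noise_sigma: float = 0.1
    vary_orientation: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise SpecError(f"need n >= 1 and m >= 1, got n={self.n}, m={self.m}")
        if self.n_clusters < 1:
            raise SpecError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if not 0.0 <= self.correlation < 1.0:
            raise SpecError(f"correlation must lie in [0, 1), got {self.correlation}")
        if self.separation < 0:
            raise SpecError(f"separation must be >= 0, got {self.separation}")
        if not self.noise_sigma > 0:
            raise SpecError(f"noise_sigma must be > 0, got {self.noise_sigma}")


def make_synthetic(spec: SyntheticSpec) -> tuple[NumericDataset, np.ndarray]:
    """Draw one complete dataset; returns (dataset, generating labels)."""
    rng = np.random.default_rng(spec.seed)
    m, k = spec.m, spec.n_clusters

    # equicorrelation covariance: unit variances, constant off-diagonal rho
    cov = np.full((m, m), spec.correlation)
    np.fill_diagonal(cov, 1.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:  # pragma: no cover - rho in [0,1) is always PD
        raise SpecError(f"correlation {spec.correlation} infeasible for m={m}")

    direction = np.ones(m) / np.sqrt(m)
    offsets = (np.arange(k) - (k - 1) / 2.0) * spec.separation

    sizes = np.full(k, spec.n // k)
    sizes[: spec.n % k] += 1
    blocks, labels = [], []
    for ck in range(k):
        z = rng.standard_normal((sizes[ck], m))
        x = z @ chol.T
        if spec.vary_orientation and ck > 0:
            signs = rng.choice([-1.0, 1.0], size=m)
            x = x * signs[None, :]
        x = x + offsets[ck] * direction[None, :]
        blocks.append(x)
        labels.extend([ck] * sizes[ck])
    values = np.vstack(blocks) + spec.noise_sigma * rng.standard_normal((spec.n, m))
    labels = np.asarray(labels, dtype=int)

    order = rng.permutation(spec.n)
    return NumericDataset(values[order]), labels[order]
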