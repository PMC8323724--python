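"""Amputation: injecting MCAR, MAR or MNAR missingness into complete data.

All three mechanisms target a missing-data ratio MDR expressed as a percent
of the V = N·M cells and stop at the first state whose achieved ratio
reaches MDR, so the overshoot is bounded by one step's share of V:

* **MCAR** removes cells one at a time at uniformly random distinct
  positions; implemented as a single draw of ``ceil(MDR·V/100)`` distinct
  cell indices, which has the same law as the one-at-a-time rejection loop
  but always terminates. Overshoot < 100/V.
* **MAR** draws one causative attribute and ``na`` distinct dependent
  attributes uniformly; the records that lose their values are the rows
  holding the smallest causative values (ties to the lowest row index),
  added in ascending causative order until the ratio is reached. The masked
  cells are exactly the cross product records × dependent attributes.
  Overshoot < 100·na/V.
* **MNAR** is MAR with the record set drawn uniformly at random instead of
  by the causative minimum — the driver of missingness is unobserved.

The causative attribute may itself be drawn as a dependent (it then loses
its own values, which makes the mechanism drift towards MNAR);
``exclude_causative=True`` redraws dependents so it cannot be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import MaskedDataset, MissingMask, NumericDataset, Provenance, as_dataset
from .exceptions import PrefilledInputError, SpecError

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass
class MissingSpec:
    """Parameters of one amputation run.

    Parameters
    ----------
    mechanism : {"MCAR", "MAR", "MNAR"}
    mdr_percent : float
        Target missing ratio in percent of all cells, strictly in (0, 100).
    na : int, optional
        Number of attributes losing values (MAR/MNAR only; ignored by MCAR).
    seed : int, optional
        Seed for the single generator driving every draw of the run.
    exclude_causative : bool
        MAR only: forbid the causative attribute from being drawn as a
        dependent attribute.
    """

    mechanism: str
    mdr_percent: float
    na: int | None = None
    seed: int | None = None
    exclude_causative: bool = False


class MissingnessAmputer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping the three mechanisms.

    ``transform`` takes a complete 2-D array and returns a float copy with
    NaNs injected; the boolean mask and the draw record are exposed as
    fitted attributes (``mask_``, ``causative_``, ``md_attributes_``,
    ``md_records_``).
    """

    def __init__(
        self,
        mechanism: str = "MCAR",
        mdr_percent: float = 10.0,
        na: int | None = None,
        exclude_causative: bool = False,
        random_state: int | None = None,
    ):
        self.mechanism = mechanism
        self.mdr_percent = mdr_percent
        self.na = na
        self.exclude_causative = exclude_causative
        self.random_state = random_state

    def _validate(self, X: np.ndarray) -> None:
        mech = str(self.mechanism).upper()
        if mech not in MECHANISMS:
            raise SpecError(f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if not (0.0 < self.mdr_percent < 100.0):
            raise SpecError(f"mdr_percent must lie strictly in (0, 100), got {self.mdr_percent}")
        if np.isnan(X).any():
            raise PrefilledInputError("amputation input already contains missing cells")
        m = X.shape[1]
        if mech != "MCAR":
            if self.na is None:
                raise SpecError(f"{mech} requires na (number of attributes losing values)")
            if not (1 <= int(self.na) <= m):
                raise SpecError(f"na must lie in [1, {m}], got {self.na}")
            if mech == "MAR" and self.exclude_causative and int(self.na) > m - 1:
                raise SpecError("exclude_causative requires na <= M - 1")

    def fit(self, X, y=None):
        X = np.asarray(as_dataset(X).values, dtype=float)
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        data = as_dataset(X)
        X = np.asarray(data.values, dtype=float).copy()
        self._validate(X)
        mech = str(self.mechanism).upper()
        n, m = X.shape
        v = n * m
        rng = np.random.default_rng(self.random_state)
        self.causative_ = None

        if mech == "MCAR":
            n_cells = math.ceil(self.mdr_percent * v / 100.0)
            flat = rng.choice(v, size=n_cells, replace=False)
            mask = np.zeros(v, dtype=bool)
            mask[flat] = True
            mask = mask.reshape(n, m)
            self.md_attributes_ = sorted({int(j) for j in flat % m})
            self.md_records_ = sorted({int(i) for i in flat // m})
        else:
            na = int(self.na)
            if mech == "MAR":
                causative = int(rng.integers(m))
                self.causative_ = causative
            attrs: list[int] = []
            for _ in range(na):
                while True:  # rejection draw, mirrors the attribute-pick loop
                    y_attr = int(rng.integers(m))
                    if y_attr in attrs:
                        continue
                    if mech == "MAR" and self.exclude_causative and y_attr == causative:
                        continue
                    break
                attrs.append(y_attr)
            n_rec = math.ceil(self.mdr_percent * v / (100.0 * na))
            if n_rec > n:
                max_ratio = 100.0 * na / m
                raise SpecError(
                    f"mdr_percent={self.mdr_percent} unreachable with na={na}: masking "
                    f"every record reaches only {max_ratio:.4g}%"
                )
            if mech == "MAR":
                # argmin-prefix of the causative column; stable => lowest
                # row index wins ties, matching repeated FindMinIndex.
                order = np.argsort(X[:, causative], kind="stable")
                records = [int(i) for i in order[:n_rec]]
            else:
                records = []
                while len(records) < n_rec:
                    x_rec = int(rng.integers(n))
                    if x_rec not in records:
                        records.append(x_rec)
            mask = np.zeros((n, m), dtype=bool)
            mask[np.ix_(records, attrs)] = True
            self.md_attributes_ = attrs
            self.md_records_ = records

        X[mask] = np.nan
        self.mask_ = mask
        self.provenance_ = Provenance(
            mechanism=mech,
            mdr_percent=float(self.mdr_percent),
            na=int(self.na) if (mech != "MCAR" and self.na is not None) else None,
            seed=self.random_state,
        )
        return X


def _run(data, spec: MissingSpec, expected: str) -> MaskedDataset:
    if str(spec.mechanism).upper() != expected:
        raise SpecError(f"spec.mechanism is {spec.mechanism!r}, expected {expected}")
    truth = as_dataset(data)
    amp = MissingnessAmputer(
        mechanism=expected,
        mdr_percent=spec.mdr_percent,
        na=spec.na,
        exclude_causative=spec.exclude_causative,
        random_state=spec.seed,
    )
    values = amp.fit(truth).transform(truth)
    masked = NumericDataset(values, list(truth.row_ids), list(truth.col_names))
    return MaskedDataset(
        data=masked,
        mask=MissingMask(amp.mask_),
        truth=truth.copy(),
        provenance=amp.provenance_,
    )


def generate_mcar(data, spec: MissingSpec) -> MaskedDataset:
    """Remove uniformly random distinct cells until the ratio reaches MDR."""
    return _run(data, spec, "MCAR")


def generate_mar(data, spec: MissingSpec) -> MaskedDataset:
    """Mask the rows with the smallest causative values in na dependent attributes."""
    return _run(data, spec, "MAR")


def generate_mnar(data, spec: MissingSpec) -> MaskedDataset:
    """Mask uniformly random distinct rows in na randomly drawn attributes."""
    return _run(data, spec, "MNAR")


def achieved_ratio(mask: MissingMask) -> float:
    """The achieved missing ratio 100·MV/V of a mask, in percent."""
    return float(100.0 * mask.flags.sum() / mask.flags.size)
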