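"""Imputation-error metrics over artificially masked cells.

RMSE, NRMSE and MAE are computed over the (predicted, observed) pairs at
the masked positions only — the cells whose true values were withheld —
with N the number of such pairs and O_max/O_min taken over the masked
cells' true values. NRMSE is therefore scale-invariant; RMSE ≥ MAE always
(quadratic vs arithmetic mean of the absolute errors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MissingMask, as_dataset
from .exceptions import DegenerateRangeError, EmptyMaskError, ShapeError


@dataclass
class MetricsReport:
    """RMSE/NRMSE/MAE over ``n_cells`` masked cells spanning ``o_range``."""

    rmse: float
    nrmse: float
    mae: float
    n_cells: int
    o_range: float


def _pair(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size:
        raise ShapeError(f"length mismatch: {pred.size} predictions vs {obs.size} observations")
    if pred.size == 0:
        raise ShapeError("metric over zero pairs is undefined")
    return pred, obs


def rmse(pred, obs) -> float:
    """Root mean square error sqrt(mean((P_i − O_i)²))."""
    pred, obs = _pair(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def nrmse(pred, obs) -> float:
    """RMSE normalised by the observed range O_max − O_min."""
    pred, obs = _pair(pred, obs)
    o_range = float(obs.max() - obs.min())
    if o_range <= 0:
        raise DegenerateRangeError("observed values span zero range; NRMSE undefined")
    return rmse(pred, obs) / o_range


def mae(pred, obs) -> float:
    """Mean absolute error mean(|P_i − O_i|)."""
    pred, obs = _pair(pred, obs)
    return float(np.mean(np.abs(pred - obs)))


def evaluate_masked(truth, mask: MissingMask, imputed) -> MetricsReport:
    """Score an imputation on exactly the cells the mask removed.

    ``nrmse`` is NaN when the masked true values span zero range.
    """
    truth = as_dataset(truth)
    imputed = as_dataset(imputed)
    if truth.shape != imputed.shape or mask.flags.shape != truth.shape:
        raise ShapeError("truth, mask and imputed shapes must agree")
    if mask.mv_count == 0:
        raise EmptyMaskError("mask selects no cells; nothing to evaluate")
    obs = truth.values[mask.flags]
    pred = imputed.values[mask.flags]
    if np.isnan(pred).any():
        raise ShapeError("imputed dataset still contains missing cells under the mask")
    o_range = float(obs.max() - obs.min())
    r = rmse(pred, obs)
    return MetricsReport(
        rmse=r,
        nrmse=r / o_range if o_range > 0 else float("nan"),
        mae=mae(pred, obs),
        n_cells=int(mask.mv_count),
        o_range=o_range,
    )
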