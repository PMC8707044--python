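"""Model accuracy metrics: R², RMSE, nRMSE and the consistency classification.

R² is the squared Pearson correlation between measured and estimated LAI
(the convention in the canopy-spectra literature; on validation data this
differs from 1 - RSS/TSS).  nRMSE is the RMSE normalized by the mean of
the measured values, in percent, and is banded into consistency classes:

    nRMSE <= 10%   excellent
    10% <  .. <= 20%  good
    20% <  .. <= 30%  moderate
    nRMSE > 30%    poor
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

CONSISTENCY_BANDS = ((10.0, "excellent"), (20.0, "good"), (30.0, "moderate"))


def _pair(measured, estimated) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(measured, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and estimated must be 1-D vectors of equal length")
    return x, y


def r_squared(measured, estimated) -> float:
    """Squared Pearson correlation between measured and estimated values.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    x, y = _pair(measured, estimated)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: R^2 undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def rmse(measured, estimated) -> float:
    """Root mean squared error, in LAI units."""
    x, y = _pair(measured, estimated)
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def nrmse(measured, estimated) -> float:
    """RMSE normalized by the mean of the measured values, in percent."""
    x, y = _pair(measured, estimated)
    xbar = x.mean()
    if xbar == 0:
        raise ValueError("mean of measured values is zero; nRMSE undefined")
    return float(100.0 * rmse(x, y) / xbar)


def consistency_class(nrmse_percent: float) -> str:
    """Band an nRMSE (%) into excellent / good / moderate / poor."""
    if nrmse_percent < 0:
        raise ValueError("nRMSE cannot be negative")
    for bound, name in CONSISTENCY_BANDS:
        if nrmse_percent <= bound:
            return name
    return "poor"


@dataclass
class AccuracyReport:
    """Accuracy of one model on one partition (modeling or validation)."""

    partition: str
    r2: float
    rmse: float
    nrmse: float
    consistency: str


def evaluate(measured, estimated, partition: str) -> AccuracyReport:
    """Compute the full metric set for one partition."""
    if partition not in ("modeling", "validation"):
        raise ValueError("partition must be 'modeling' or 'validation'")
    nr = nrmse(measured, estimated)
    return AccuracyReport(partition, r_squared(measured, estimated),
                          rmse(measured, estimated), nr, consistency_class(nr))
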