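"""Hold-out prediction-error metrics: RMSE, MAE, and MAPE (percent)."""

from __future__ import annotations

import numpy as np

__all__ = ["rmse", "mae", "mape"]


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size or a.size == 0:
        raise ValueError("actual and predicted must be non-empty and equal length")
    return a, p


def rmse(actual, predicted) -> float:
    """Root-mean-square error sqrt(mean((pred - actual)^2))."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def mae(actual, predicted) -> float:
    """Mean absolute error mean(|pred - actual|)."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(p - a)))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent. Requires actual != 0."""
    a, p = _paired(actual, predicted)
    if np.any(a == 0):
        raise ValueError("MAPE undefined when an actual value is zero")
    return float(np.mean(np.abs((p - a) / a)) * 100.0)
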