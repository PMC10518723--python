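"""Regression evaluation metrics.

Population (1/n) conventions throughout: MSE, RMSE, MAE, cosine
distance (1 minus cosine similarity; 0 parallel, 1 orthogonal,
2 antiparallel), plus the Pearson correlation between predictions and
targets with its two-sided p-value on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats


def _check(y_hat, y) -> tuple[np.ndarray, np.ndarray]:
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y_hat, y


def mse(y_hat, y) -> float:
    y_hat, y = _check(y_hat, y)
    d = y_hat - y
    return float(np.mean(d * d))


def rmse(y_hat, y) -> float:
    return float(np.sqrt(mse(y_hat, y)))


def mae(y_hat, y) -> float:
    y_hat, y = _check(y_hat, y)
    return float(np.mean(np.abs(y_hat - y)))


def cos_distance(y_hat, y) -> float:
    y_hat, y = _check(y_hat, y)
    nh, ny = np.linalg.norm(y_hat), np.linalg.norm(y)
    if nh == 0 or ny == 0:
        raise ValueError("cosine distance undefined for a zero-norm vector")
    return float(1.0 - np.dot(y_hat, y) / (nh * ny))


def pearson_with_p(y_hat, y) -> tuple[float, float]:
    """Pearson r and the two-sided p-value from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    y_hat, y = _check(y_hat, y)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y_hat) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r, p = stats.pearsonr(y_hat, y)
    return float(r), float(p)


@dataclass(frozen=True)
class MetricsReport:
    """One model's scores on one evaluation set."""

    mse: float
    rmse: float
    mae: float
    cos_distance: float
    pearson_r: float
    p_value: float
    n_rules: int = 0
    train_time_s: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    y_hat, y, n_rules: int = 0, train_time_s: float = 0.0
) -> MetricsReport:
    r, p = pearson_with_p(y_hat, y)
    return MetricsReport(
        mse=mse(y_hat, y),
        rmse=rmse(y_hat, y),
        mae=mae(y_hat, y),
        cos_distance=cos_distance(y_hat, y),
        pearson_r=r,
        p_value=p,
        n_rules=n_rules,
        train_time_s=train_time_s,
    )
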