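"""Tabular cleaning, [0,1] normalization and correlation-based feature selection.

The pipeline mirrors standard practice for small clinical regression
cohorts: drop any row containing a missing value, min-max scale the
continuous columns to [0,1] using *training-set* constants, and keep the
features whose Pearson correlation with the target is either
statistically significant (p-value at or below a threshold) or of
meaningful magnitude (|r| at or above a threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from anfisbpso.errors import (
    ConstantColumnError,
    EmptyDatasetError,
    EmptySelectionError,
    ZeroVarianceFeatureError,
)

BINARY = "binary"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class Dataset:
    """Feature matrix ``X`` (rows = samples), target ``y`` and column metadata.

    ``kinds`` flags each column as ``"binary"`` (0/1 indicator) or
    ``"continuous"``; only continuous columns are min-max scaled.
    ``norm_constants`` records per-column (min, max) after normalization
    so the identical affine map can be replayed on held-out data.
    """

    X: np.ndarray
    y: np.ndarray
    names: tuple[str, ...]
    kinds: tuple[str, ...]
    norm_constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "kinds", tuple(self.kinds))
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if X.shape[1] != len(self.names) or len(self.names) != len(self.kinds):
            raise ValueError("names/kinds length must match the number of columns")
        bad = set(self.kinds) - {BINARY, CONTINUOUS}
        if bad:
            raise ValueError(f"unknown column kinds: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]

    def subset(self, names: list[str] | tuple[str, ...]) -> "Dataset":
        """Restrict to the named feature columns, in dataset order."""
        keep = [n for n in self.names if n in set(names)]
        idx = [self.names.index(n) for n in keep]
        return replace(
            self,
            X=self.X[:, idx],
            names=tuple(keep),
            kinds=tuple(self.kinds[i] for i in idx),
            norm_constants={k: v for k, v in self.norm_constants.items() if k in keep},
        )

    def to_frame(self, target_name: str = "target") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.names))
        df[target_name] = self.y
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        target: str,
        kinds: dict[str, str] | None = None,
    ) -> "Dataset":
        """Build a dataset from a dataframe; columns with values only in
        {0, 1, NaN} are auto-flagged binary unless ``kinds`` overrides."""
        if target not in df.columns:
            raise KeyError(f"target column {target!r} not in dataframe")
        feats = [c for c in df.columns if c != target]
        X = df[feats].to_numpy(dtype=float)
        y = df[target].to_numpy(dtype=float)
        kinds = kinds or {}
        inferred = []
        for j, c in enumerate(feats):
            if c in kinds:
                inferred.append(kinds[c])
            else:
                col = X[:, j]
                vals = np.unique(col[~np.isnan(col)])
                inferred.append(BINARY if np.isin(vals, [0.0, 1.0]).all() else CONTINUOUS)
        return cls(X=X, y=y, names=tuple(feats), kinds=tuple(inferred))


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature Pearson r with the target and its two-sided p-value."""

    names: tuple[str, ...]
    r: np.ndarray
    p_value: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.names, "r": self.r, "p_value": self.p_value}
        )


def read_csv(path, target: str, kinds: dict[str, str] | None = None) -> Dataset:
    """Read a headered CSV; empty cells become NaN (missing markers)."""
    return Dataset.from_frame(pd.read_csv(path), target=target, kinds=kinds)


def write_csv(data: Dataset, path, target_name: str = "target") -> None:
    data.to_frame(target_name).to_csv(path, index=False)


def remove_missing(data: Dataset) -> Dataset:
    """Drop every row that contains at least one missing value (in X or y).

    Row order is preserved; idempotent. Raises :class:`EmptyDatasetError`
    if no complete row remains.
    """
    table = np.column_stack([data.X, data.y])
    keep = ~np.isnan(table).any(axis=1)
    if not keep.any():
        raise EmptyDatasetError("all rows contain missing values; nothing left")
    return replace(data, X=data.X[keep], y=data.y[keep])


def minmax_normalize(
    data: Dataset,
    columns: list[str] | tuple[str, ...] | None = None,
    constants: dict[str, tuple[float, float]] | None = None,
) -> Dataset:
    """Map each named continuous column through (x - min) / (max - min).

    With ``constants`` given (training-set minima/maxima), replays that
    transform instead of refitting — required for held-out folds. The
    fitted constants are recorded on the returned dataset.
    """
    if columns is None:
        columns = [n for n, k in zip(data.names, data.kinds) if k == CONTINUOUS]
    for c in columns:
        if c not in data.names:
            raise KeyError(f"unknown column {c!r}")
    X = data.X.copy()
    fitted = dict(data.norm_constants)
    for c in columns:
        j = data.names.index(c)
        if constants is not None:
            lo, hi = constants[c]
        else:
            lo, hi = float(np.min(X[:, j])), float(np.max(X[:, j]))
        if hi <= lo:
            raise ConstantColumnError(f"column {c!r} is constant (min == max == {lo})")
        X[:, j] = (X[:, j] - lo) / (hi - lo)
        fitted[c] = (lo, hi)
    return replace(data, X=X, norm_constants=fitted)


def inverse_normalize(data: Dataset) -> Dataset:
    """Undo :func:`minmax_normalize` using the recorded constants."""
    X = data.X.copy()
    for c, (lo, hi) in data.norm_constants.items():
        j = data.names.index(c)
        X[:, j] = X[:, j] * (hi - lo) + lo
    return replace(data, X=X, norm_constants={})


def compute_feature_stats(data: Dataset) -> FeatureStats:
    """Pearson r of each feature with the target plus the two-sided p-value
    from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom."""
    n = data.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for a p-value")
    if np.isnan(data.X).any() or np.isnan(data.y).any():
        raise ValueError("dataset contains missing values; clean it first")
    rs, ps = [], []
    for j, name in enumerate(data.names):
        col = data.X[:, j]
        if np.ptp(col) == 0.0:
            raise ZeroVarianceFeatureError(
                f"feature {name!r} has zero variance; correlation undefined"
            )
        r, p = stats.pearsonr(col, data.y)
        rs.append(float(r))
        ps.append(float(p))
    return FeatureStats(names=data.names, r=np.array(rs), p_value=np.array(ps))


def select_features(
    stats_: FeatureStats,
    p_threshold: float = 0.05,
    r_threshold: float = 0.1,
    exclude: list[str] | tuple[str, ...] | set[str] = (),
) -> list[str]:
    """Keep features with p <= p_threshold OR |r| >= r_threshold, minus
    ``exclude``; the disjunction admits features that are either
    significant or of non-trivial effect size. Input order is preserved.
    """
    if p_threshold <= 0 or r_threshold <= 0:
        raise ValueError("thresholds must be positive")
    exclude = set(exclude)
    unknown = exclude - set(stats_.names)
    if unknown:
        raise KeyError(f"exclude labels not in stats: {sorted(unknown)}")
    selected = [
        name
        for name, r, p in zip(stats_.names, stats_.r, stats_.p_value)
        if name not in exclude and (p <= p_threshold or abs(r) >= r_threshold)
    ]
    if not selected:
        raise EmptySelectionError(
            "no feature passed the filter; consider relaxing p_threshold "
            f"(={p_threshold}) or r_threshold (={r_threshold})"
        )
    return selected
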