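"""Experiment protocol: cleaning, feature selection, k-fold CV, model zoo.

Reproduces the published validation protocol — drop incomplete rows,
select features by the p-value/correlation filter on the full cleaned
cohort, then 5-fold cross-validation in which each fold's held-out 20%
plays the test split. Fuzzy models (conventional ANFIS and the
BPSO-pruned variant) are compared, optionally alongside linear
regression, a shallow one-hidden-layer network and a support-vector
regressor fitted on the identical preprocessed folds.

Feature selection deliberately precedes the CV loop, mirroring the
published sequence; see the methods note for the leakage caveat. All
normalization constants inside a fold come from that fold's training
portion only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from anfisbpso import anfis, preprocessing, selector
from anfisbpso.anfis import AnfisConfig
from anfisbpso.bpso import SwarmConfig
from anfisbpso.metrics import MetricsReport, evaluate
from anfisbpso.preprocessing import CONTINUOUS, Dataset
from anfisbpso.synthetic import SyntheticSpec, generate

logger = logging.getLogger(__name__)

FUZZY_MODELS = ("anfis", "anfis_bpso")
BASELINE_MODELS = ("linear", "shallow_nn", "svr")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun an experiment bit-for-bit."""

    data_path: str | None = None
    synth_spec: SyntheticSpec | None = None
    target: str = "target"
    p_threshold: float = 0.05
    r_threshold: float = 0.1
    exclude: tuple[str, ...] = ()
    anfis: AnfisConfig = field(default_factory=AnfisConfig)
    swarm: dict = field(default_factory=dict)  # SwarmConfig overrides (dim/seed set per fold)
    folds: int = 5
    test_fraction: float = 0.2
    holdout: bool = False  # single fixed 80/20 split instead of k-fold
    normalize_target: bool = True
    models: tuple[str, ...] = FUZZY_MODELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0,1)")
        unknown = set(self.models) - set(FUZZY_MODELS + BASELINE_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if (self.data_path is None) == (self.synth_spec is None):
            raise ValueError("provide exactly one of data_path or synth_spec")


@dataclass
class FoldResult:
    metrics: MetricsReport
    y_true: np.ndarray
    y_pred: np.ndarray


@dataclass
class ExperimentReport:
    """Per-model, per-fold metrics plus aggregates and run metadata."""

    config: ExperimentConfig
    selected_features: list[str]
    feature_stats: pd.DataFrame
    folds: dict[str, list[FoldResult]]
    failures: dict[str, str]
    timestamp: str = ""
    wall_time_s: float = 0.0

    _METRIC_FIELDS = ("mse", "mae", "rmse", "cos_distance", "p_value", "pearson_r", "n_rules", "train_time_s")

    def aggregate(self) -> pd.DataFrame:
        """Mean (+/- std) of each metric over folds, one row per model."""
        rows = []
        for model, folds in self.folds.items():
            row: dict = {"model": model, "n_folds": len(folds)}
            for m in self._METRIC_FIELDS:
                vals = np.array([getattr(f.metrics, m) for f in folds], dtype=float)
                row[f"{m}_mean"] = float(vals.mean())
                row[f"{m}_std"] = float(vals.std(ddof=0)) if len(vals) > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for model, folds in self.folds.items():
            for i, f in enumerate(folds):
                rows.append({"model": model, "fold": i, **f.metrics.to_dict()})
        return pd.DataFrame(rows)

    def to_dict(self, include_times: bool = True) -> dict:
        doc = {
            "config": _config_dict(self.config),
            "selected_features": list(self.selected_features),
            "feature_stats": self.feature_stats.to_dict(orient="list"),
            "folds": {
                model: [
                    {
                        "metrics": f.metrics.to_dict(),
                        "y_true": f.y_true.tolist(),
                        "y_pred": f.y_pred.tolist(),
                    }
                    for f in folds
                ]
                for model, folds in self.folds.items()
            },
            "failures": dict(self.failures),
        }
        if include_times:
            doc["timestamp"] = self.timestamp
            doc["wall_time_s"] = self.wall_time_s
        else:
            for folds in doc["folds"].values():
                for f in folds:
                    f["metrics"].pop("train_time_s", None)
        return doc

    def canonical_json(self) -> str:
        """Deterministic serialization: identical config + seeds give a
        byte-identical string (wall-clock fields excluded)."""
        return json.dumps(self.to_dict(include_times=False), sort_keys=True)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(include_times=True), indent=2)


def _config_dict(cfg: ExperimentConfig) -> dict:
    doc = asdict(cfg)
    if cfg.synth_spec is not None:
        doc["synth_spec"] = asdict(cfg.synth_spec)
    return doc


def _load(cfg: ExperimentConfig) -> Dataset:
    if cfg.data_path is not None:
        return preprocessing.read_csv(cfg.data_path, target=cfg.target)
    return generate(cfg.synth_spec)


def _fold_seed(seed: int, fold: int, salt: int) -> int:
    return int((seed * 100003 + fold * 1009 + salt) % (2**31))


def _fit_predict(
    name: str,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    cfg: ExperimentConfig,
    fold: int,
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Train one model; returns (train preds, test preds, n_rules, seconds)."""
    t0 = time.perf_counter()
    if name == "anfis":
        model = anfis.build_model(Xtr.shape[1], cfg.anfis)
        model, _ = anfis.train_hybrid(model, Xtr, ytr)
        tr, te = anfis.predict(model, Xtr), anfis.predict(model, Xte)
        return tr, te, model.n_rules, time.perf_counter() - t0
    if name == "anfis_bpso":
        n_rules = cfg.anfis.n_mfs ** Xtr.shape[1]
        swarm = SwarmConfig(
            **{
                **cfg.swarm,
                "dim": n_rules,
                "seed": _fold_seed(cfg.seed, fold, salt=7),
            }
        )
        result = selector.train_anfis_bpso(Xtr, ytr, cfg.anfis, swarm)
        tr = selector.predict(result, Xtr)
        te = selector.predict(result, Xte)
        return tr, te, result.n_rules_selected, time.perf_counter() - t0
    if name == "linear":
        from sklearn.linear_model import LinearRegression

        est = LinearRegression()
    elif name == "shallow_nn":
        from sklearn.neural_network import MLPRegressor

        est = MLPRegressor(
            hidden_layer_sizes=(10,),
            max_iter=5000,
            random_state=_fold_seed(cfg.seed, fold, salt=11),
        )
    elif name == "svr":
        from sklearn.svm import SVR

        est = SVR(kernel="rbf")
    else:
        raise ValueError(f"unknown model {name!r}")
    est.fit(Xtr, ytr)
    return est.predict(Xtr), est.predict(Xte), 0, time.perf_counter() - t0


def _splits(cfg: ExperimentConfig, n: int):
    if cfg.holdout:
        idx = np.arange(n)
        tr, te = train_test_split(
            idx, test_size=cfg.test_fraction, random_state=cfg.seed % (2**31)
        )
        return [(tr, te)]
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed % (2**31))
    return list(kf.split(np.arange(n)))


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Run the full pipeline and return the report."""
    t0 = time.perf_counter()
    raw = _load(cfg)
    clean = preprocessing.remove_missing(raw)
    stats = preprocessing.compute_feature_stats(clean)
    selected = preprocessing.select_features(
        stats, cfg.p_threshold, cfg.r_threshold, exclude=cfg.exclude
    )
    stats_df = stats.to_frame()
    stats_df["selected"] = [n in selected for n in stats.names]
    data = clean.subset(selected)

    cont = [n for n, k in zip(data.names, data.kinds) if k == CONTINUOUS]
    folds: dict[str, list[FoldResult]] = {m: [] for m in cfg.models}
    failures: dict[str, str] = {}
    for fold, (tr_idx, te_idx) in enumerate(_splits(cfg, data.n_samples)):
        train = Dataset(
            X=data.X[tr_idx], y=data.y[tr_idx], names=data.names, kinds=data.kinds
        )
        test = Dataset(
            X=data.X[te_idx], y=data.y[te_idx], names=data.names, kinds=data.kinds
        )
        train = preprocessing.minmax_normalize(train, cont)
        test = preprocessing.minmax_normalize(test, cont, constants=train.norm_constants)
        ytr, yte = train.y, test.y
        if cfg.normalize_target:
            lo, hi = float(ytr.min()), float(ytr.max())
            if hi <= lo:
                raise preprocessing.ConstantColumnError("constant training target")
            ytr = (ytr - lo) / (hi - lo)
            yte = (yte - lo) / (hi - lo)
        for name in cfg.models:
            try:
                _, te_pred, n_rules, secs = _fit_predict(
                    name, train.X, ytr, test.X, cfg, fold
                )
                rep = evaluate(te_pred, yte, n_rules=n_rules, train_time_s=secs)
                folds[name].append(
                    FoldResult(metrics=rep, y_true=yte, y_pred=te_pred)
                )
            except Exception as exc:  # per-model isolation
                logger.exception("model %s failed on fold %d", name, fold)
                failures[f"{name}/fold{fold}"] = f"{type(exc).__name__}: {exc}"
    return ExperimentReport(
        config=cfg,
        selected_features=list(selected),
        feature_stats=stats_df,
        folds={m: f for m, f in folds.items() if f},
        failures=failures,
        timestamp=datetime.now(timezone.utc).isoformat(),
        wall_time_s=time.perf_counter() - t0,
    )


def render_report(report: ExperimentReport) -> str:
    """Human-readable table: one row per model, mean(+/-std) per metric."""
    agg = report.aggregate()
    lines = [
        f"{'model':<12} {'MSE':>16} {'MAE':>16} {'RMSE':>16} "
        f"{'Cos':>16} {'p-value':>10} {'corr':>8} {'#rules':>14} {'time(s)':>14}"
    ]
    for _, row in agg.iterrows():
        def pm(m, prec=4):
            return f"{row[f'{m}_mean']:.{prec}f}(+/-{row[f'{m}_std']:.{prec}f})"

        lines.append(
            f"{row['model']:<12} {pm('mse'):>16} {pm('mae'):>16} {pm('rmse'):>16} "
            f"{pm('cos_distance'):>16} {row['p_value_mean']:>10.2e} "
            f"{row['pearson_r_mean']:>8.4f} "
            f"{row['n_rules_mean']:.1f}(+/-{row['n_rules_std']:.2f})".ljust(14)
            + f" {row['train_time_s_mean']:.1f}(+/-{row['train_time_s_std']:.1f})"
        )
    if report.failures:
        lines.append(f"failures: {report.failures}")
    return "\n".join(lines)


def write_report(report: ExperimentReport, outdir) -> None:
    """Write report artifacts: aggregate CSV, fold CSV, full JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.aggregate().to_csv(outdir / "report_aggregate.csv", index=False)
    report.fold_table().to_csv(outdir / "report_folds.csv", index=False)
    (outdir / "report.json").write_text(report.to_json())
    report.feature_stats.to_csv(outdir / "feature_stats.csv", index=False)


def plot_fold_predictions(report: ExperimentReport, path) -> None:
    """Per-fold line plot of actual vs predicted targets for each model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = list(report.folds)
    n_folds = max(len(f) for f in report.folds.values())
    fig, axes = plt.subplots(
        len(models), n_folds, figsize=(3 * n_folds, 2.5 * len(models)), squeeze=False
    )
    for i, model in enumerate(models):
        for j, fold in enumerate(report.folds[model]):
            ax = axes[i][j]
            ax.plot(fold.y_true, label="actual", lw=1)
            ax.plot(fold.y_pred, label="predicted", lw=1, ls="--")
            ax.set_title(f"{model} fold {j}", fontsize=8)
            if i == 0 and j == 0:
                ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
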