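"""Univariate feature selection, baseline regressors, and the
models x feature-fractions benchmarking grid.

Feature importance is the univariate linear-regression F statistic of each
descriptor against the activity score, F = (n-2) r^2 / (1 - r^2), computed
on training rows only.  Baselines (lasso, ridge, random forest, SVR) are
fit with an exhaustive hyperparameter grid search scored by validation
RMSE; the conv-net families reuse the deep trainer.  The benchmark grid
crosses model families with top-q% feature fractions and reports test-set
metrics per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.svm import SVR

from . import deepmodel
from .assaydata import (
    AssayTable,
    DescriptorTable,
    DatasetSplit,
    ModelArrays,
    apply_normalization,
    fit_normalization,
)
from .deepmodel import ConcentrationScaler, PredictionSet, TrainConfig
from .metrics import EvalReport, regression_metrics

__all__ = [
    "FeatureScore",
    "BaselineSpec",
    "FittedBaseline",
    "BenchmarkReport",
    "univariate_feature_scores",
    "select_top_fraction",
    "fit_baseline",
    "run_benchmark_grid",
    "DEFAULT_GRIDS",
]

ML_FAMILIES = ("lasso", "ridge", "random_forest", "svr")
DEEP_FAMILIES = ("deepmgo", "deepic50_like", "resnet18_like")

#: default hyperparameter grids; the published grids live in a
#: supplementary table and can be supplied explicitly instead.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lasso": {"alpha": np.logspace(-4, 2, 7).tolist()},
    "ridge": {"alpha": np.logspace(-4, 2, 7).tolist()},
    "random_forest": {"n_estimators": [100, 500], "max_depth": [None, 16]},
    "svr": {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1]},
}


@dataclass
class FeatureScore:
    feature_name: str
    f_statistic: float
    rank: int  # 1 = most important


def univariate_feature_scores(X: np.ndarray, y: np.ndarray) -> list[FeatureScore]:
    """Score each feature by its univariate regression F statistic.

    F = (n-2) r^2 / (1-r^2) with r the Pearson correlation of the single
    feature with y; monotone in r^2 at fixed n, so the ranking equals the
    r^2 ranking.  Zero-variance features score 0 and rank last; a feature
    identical to y gets an infinite score.  Ties break by column order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need n >= 3 for the univariate F test")
    if y.shape[0] != n:
        raise ValueError("X and y are not aligned")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = math.sqrt(float((yc**2).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
        r2 = np.clip(r**2, 0.0, 1.0)
        f = np.where(sx == 0, 0.0, np.where(r2 >= 1.0, np.inf, (n - 2) * r2 / (1.0 - r2)))
    # sort: finite/infinite F descending, zero-variance always last, ties by column order
    dead = sx == 0
    order = sorted(range(p), key=lambda j: (bool(dead[j]), -f[j] if not dead[j] else 0.0, j))
    ranks = np.empty(p, dtype=int)
    for pos, j in enumerate(order):
        ranks[j] = pos + 1
    return [FeatureScore(f"f{j}", float(f[j]), int(ranks[j])) for j in range(p)]


def scores_with_names(
    X: np.ndarray, y: np.ndarray, feature_names: Sequence[str]
) -> list[FeatureScore]:
    scores = univariate_feature_scores(X, y)
    for s, name in zip(scores, feature_names):
        s.feature_name = name
    return scores


def select_top_fraction(scores: list[FeatureScore], q: float) -> list[str]:
    """Keep the floor(q*p/100) best-ranked features (minimum 1).

    The subset is returned in the original column order; q=100 is the
    identity.
    """
    if not 0 < q <= 100:
        raise ValueError(f"fraction must be in (0, 100], got {q}")
    p = len(scores)
    k = max(1, int(math.floor(q * p / 100.0)))
    keep = {s.feature_name for s in scores if s.rank <= k}
    return [s.feature_name for s in scores if s.feature_name in keep]


# ---------------------------------------------------------------------------
# baselines


@dataclass
class BaselineSpec:
    family: str
    hyperparameter_grid: dict[str, list] | None = None
    seed: int = 0
    train_config: TrainConfig | None = None  # deep families only

    def __post_init__(self) -> None:
        if self.family not in ML_FAMILIES + DEEP_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ML_FAMILIES:
            if self.hyperparameter_grid is None:
                self.hyperparameter_grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
            if not self.hyperparameter_grid or any(
                len(v) == 0 for v in self.hyperparameter_grid.values()
            ):
                raise ValueError(f"empty hyperparameter grid for tunable family {self.family!r}")


@dataclass
class FittedBaseline:
    family: str
    model: object  # sklearn estimator or deepmodel.TrainedModel
    chosen_hyperparameters: dict
    validation_rmse: float
    conc_scaler: ConcentrationScaler | None = None

    def predict(self, arrays: ModelArrays) -> np.ndarray:
        if self.family in DEEP_FAMILIES:
            return self.model.predict_normalized(arrays.X, arrays.concentration)
        design = np.column_stack([arrays.X, self.conc_scaler.transform(arrays.concentration)])
        return np.asarray(self.model.predict(design))


def _make_estimator(family: str, params: dict, seed: int):
    if family == "lasso":
        return Lasso(max_iter=50_000, **params)
    if family == "ridge":
        return Ridge(**params)
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == "svr":
        return SVR(kernel="rbf", **params)
    raise ValueError(family)


def fit_baseline(spec: BaselineSpec, train: ModelArrays, val: ModelArrays) -> FittedBaseline:
    """Exhaustive grid search scored by validation RMSE; ties keep grid order.

    The winning hyperparameter set is refit on the training rows and
    returned.  Deep families have no grid: they train once with their
    TrainConfig on the same train/val contract.
    """
    if spec.family in DEEP_FAMILIES:
        cfg = spec.train_config or TrainConfig(seed=spec.seed)
        p = train.X.shape[1]
        if spec.family == "deepmgo":
            net_spec = deepmodel.compact_spec(p) if p < 800 else deepmodel.reference_spec(p)
            net = deepmodel.build_deepmgo(net_spec, seed=cfg.seed)
        elif spec.family == "deepic50_like":
            net = deepmodel.build_network(deepmodel.deepic50_like_spec(p), seed=cfg.seed)
        else:
            net = deepmodel.build_network(deepmodel.resnet18_like_spec(p), seed=cfg.seed)
        # normalization already applied upstream; carry a width-matched stub
        from .assaydata import NormalizationState

        state = NormalizationState(
            feature_names=[f"f{j}" for j in range(p)],
            feature_min=np.zeros(p),
            feature_max=np.ones(p),
            activity_mean=0.0,
            activity_sd=1.0,
            fit_on="pre-normalized benchmark arrays",
        )
        trained = deepmodel.train_model(net, train, cfg, state, val=val)
        val_rmse = trained.history["val_loss"][-1] if trained.history["val_loss"] else float("nan")
        return FittedBaseline(
            family=spec.family,
            model=trained,
            chosen_hyperparameters={},
            validation_rmse=float(val_rmse),
        )

    scaler = ConcentrationScaler.fit(train.concentration)
    Xtr = np.column_stack([train.X, scaler.transform(train.concentration)])
    Xva = np.column_stack([val.X, scaler.transform(val.concentration)])
    names = list(spec.hyperparameter_grid.keys())
    best: tuple[float, dict] | None = None
    for combo in product(*(spec.hyperparameter_grid[k] for k in names)):
        params = dict(zip(names, combo))
        est = _make_estimator(spec.family, params, spec.seed)
        est.fit(Xtr, train.y)
        rmse = float(np.sqrt(np.mean((est.predict(Xva) - val.y) ** 2)))
        if best is None or rmse < best[0]:  # strict <: ties keep the earlier grid point
            best = (rmse, params)
    final = _make_estimator(spec.family, best[1], spec.seed)
    final.fit(Xtr, train.y)
    return FittedBaseline(
        family=spec.family,
        model=final,
        chosen_hyperparameters=best[1],
        validation_rmse=best[0],
        conc_scaler=scaler,
    )


# ---------------------------------------------------------------------------
# the benchmark grid


@dataclass
class BenchmarkReport:
    cells: dict[tuple[str, float], EvalReport]
    best_cell: tuple[str, float] | None
    errors: dict[tuple[str, float], str] = field(default_factory=dict)
    selected_counts: dict[float, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": fam,
                "fraction": frac,
                "r2": rep.r2,
                "log2_rmse": rep.log2_rmse,
                "rmse": rep.rmse,
                "pcc": rep.pcc,
                "n_test": rep.n,
            }
            for (fam, frac), rep in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def _subset(arrays: ModelArrays, cols: np.ndarray) -> ModelArrays:
    return ModelArrays(
        X=arrays.X[:, cols],
        concentration=arrays.concentration,
        y=arrays.y,
        compound_ids=arrays.compound_ids,
    )


def run_benchmark_grid(
    families: Sequence[str],
    fractions: Sequence[float],
    descriptors: DescriptorTable,
    assays: AssayTable,
    split: DatasetSplit,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    grids: dict[str, dict[str, list]] | None = None,
) -> BenchmarkReport:
    """Cross model families with top-q% feature fractions.

    The split is fixed once; normalization and feature importance are fit
    on training rows only.  Every cell holds the test-set EvalReport; a
    failing cell is recorded and the grid continues.
    """
    state = fit_normalization(descriptors, assays, split.train_idx)
    arrays = apply_normalization(state, descriptors, assays)

    def take(idx: np.ndarray) -> ModelArrays:
        return ModelArrays(
            X=arrays.X[idx],
            concentration=arrays.concentration[idx],
            y=arrays.y[idx],
            compound_ids=[arrays.compound_ids[i] for i in idx],
        )

    train, val, test = take(split.train_idx), take(split.val_idx), take(split.test_idx)
    scores = scores_with_names(train.X, train.y, descriptors.feature_names)
    name_to_col = {n: j for j, n in enumerate(descriptors.feature_names)}

    cells: dict[tuple[str, float], EvalReport] = {}
    errors: dict[tuple[str, float], str] = {}
    selected_counts: dict[float, int] = {}
    for frac in fractions:
        kept = select_top_fraction(scores, frac)
        cols = np.array([name_to_col[n] for n in kept], dtype=int)
        selected_counts[frac] = cols.size
        tr, va, te = (_subset(a, cols) for a in (train, val, test))
        for fam in families:
            try:
                cfg = None
                if fam in DEEP_FAMILIES and train_config is not None:
                    cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
                spec = BaselineSpec(
                    family=fam,
                    hyperparameter_grid=(grids or {}).get(fam),
                    seed=seed,
                    train_config=cfg,
                )
                fitted = fit_baseline(spec, tr, va)
                preds = PredictionSet(observed=te.y, predicted=fitted.predict(te))
                cells[(fam, float(frac))] = regression_metrics(preds)
            except Exception as exc:  # record and continue
                errors[(fam, float(frac))] = f"{type(exc).__name__}: {exc}"
    best = max(cells, key=lambda k: cells[k].r2) if cells else None
    return BenchmarkReport(cells=cells, best_cell=best, errors=errors, selected_counts=selected_counts)
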