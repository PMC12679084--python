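"""Regression metrics and binary-validation ROC analysis.

Regression: RMSE, log2(RMSE), the coefficient of determination
R^2 = 1 - SS_res / SS_tot, and Pearson's correlation (PCC).  Binary
validation of the score as a classifier: AUROC by the Mann-Whitney
convention (ties credit 1/2), a stratified percentile-bootstrap 95% CI,
and the optimal cutoff maximizing Youden's J.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .deepmodel import PredictionSet

__all__ = [
    "EvalReport",
    "ROCReport",
    "regression_metrics",
    "roc_auc",
    "auroc_ci",
    "optimal_cutoff",
    "roc_report",
]


@dataclass
class EvalReport:
    rmse: float
    log2_rmse: float
    r2: float
    pcc: float
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "log2_rmse": self.log2_rmse, "r2": self.r2, "pcc": self.pcc, "n": self.n}


@dataclass
class ROCReport:
    auroc: float
    ci: tuple[float, float]
    optimal_cutoff: float
    youden_j: float
    n_pos: int
    n_neg: int
    bootstrap: tuple[int, int]  # (replicates, seed)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "optimal_cutoff": self.optimal_cutoff,
            "youden_j": self.youden_j,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "bootstrap_replicates": self.bootstrap[0],
            "bootstrap_seed": self.bootstrap[1],
        }


def regression_metrics(preds: PredictionSet) -> EvalReport:
    """RMSE, log2(RMSE), R^2 and PCC of predicted vs observed scores.

    ``log2_rmse`` is ``-inf`` (sentinel) when RMSE is exactly 0; R^2 may be
    negative for predictors worse than the observed mean.  A constant
    observed vector leaves R^2 and PCC undefined and raises.
    """
    y, p = preds.observed, preds.predicted
    if preds.n < 2:
        raise ValueError("need n >= 2 for R^2 / PCC")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant observed vector: R^2 and PCC undefined")
    rmse = float(np.sqrt(np.mean((y - p) ** 2)))
    r2 = 1.0 - float(np.sum((y - p) ** 2)) / ss_tot
    if np.all(p == p[0]):
        pcc = float("nan")  # constant predictions have no correlation
    else:
        pcc = float(stats.pearsonr(y, p).statistic)
    log2_rmse = math.log2(rmse) if rmse > 0 else float("-inf")
    return EvalReport(rmse=rmse, log2_rmse=log2_rmse, r2=r2, pcc=pcc, n=preds.n)


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    return labels, pos


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC by pair counting with 1/2 credit for ties (Mann-Whitney).

    Computed from midranks: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg),
    identical to enumerating all positive-negative score pairs.
    """
    labels, pos = _check_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)  # midranks give the 1/2 tie credit
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_ci(
    labels: np.ndarray,
    scores: np.ndarray,
    replicates: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% percentile bootstrap CI for the AUROC, stratified by class.

    Positives and negatives are resampled within class so every replicate
    contains both classes; the interval is the empirical 2.5/97.5
    percentile of the replicate AUROCs.
    """
    if replicates < 100:
        raise ValueError("need >= 100 bootstrap replicates")
    labels, pos = _check_classes(labels)
    scores = np.asarray(scores, dtype=float)
    s_pos, s_neg = scores[pos], scores[~pos]
    rng = np.random.default_rng(seed)
    n_pos, n_neg = s_pos.size, s_neg.size
    aucs = np.empty(replicates)
    for r in range(replicates):
        bp = s_pos[rng.integers(0, n_pos, n_pos)]
        bn = s_neg[rng.integers(0, n_neg, n_neg)]
        ranks = stats.rankdata(np.concatenate([bp, bn]))
        u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs[r] = u / (n_pos * n_neg)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def optimal_cutoff(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    A compound is called active when its score is strictly greater than the
    threshold.  Candidates are midpoints between adjacent sorted unique
    scores plus one boundary candidate below all scores; ties take the
    lowest threshold.  Returns ``(cutoff, J)``; J <= 0 (anti-separated
    data) is reported with a warning.
    """
    labels, pos = _check_classes(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    candidates = [float(uniq[0]) - 1.0]
    candidates.extend(((uniq[:-1] + uniq[1:]) / 2.0).tolist())
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        called = scores > t
        sens = float((called & pos).sum()) / n_pos
        spec = float((~called & ~pos).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j:  # strict: ties keep the lowest threshold
            best_t, best_j = t, j
    if best_j <= 0:
        warnings.warn(f"optimal Youden J = {best_j:.3f} <= 0: scores do not separate the classes")
    return float(best_t), float(best_j)


def roc_report(
    labels: np.ndarray,
    scores: np.ndarray,
    replicates: int = 2000,
    seed: int = 0,
) -> ROCReport:
    """Full binary-validation report: AUROC, bootstrap CI, Youden cutoff."""
    labels, pos = _check_classes(labels)
    auc = roc_auc(labels, scores)
    ci = auroc_ci(labels, scores, replicates=replicates, seed=seed)
    cutoff, j = optimal_cutoff(labels, scores)
    return ROCReport(
        auroc=auc,
        ci=ci,
        optimal_cutoff=cutoff,
        youden_j=j,
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
        bootstrap=(replicates, seed),
    )
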