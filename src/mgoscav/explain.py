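"""Model-agnostic Shapley-value explanations of the score predictor.

The value of a feature coalition S is the model output averaged over a
background sample with the absent features replaced by background values,

    v(S) = mean_b f(x_S, b_{\\bar S}),

and a feature's attribution phi_i is its Shapley value under v.  For small
feature counts (p <= 12) all 2^p coalitions are enumerated, which makes the
local-accuracy, symmetry and dummy axioms hold exactly; for wider models
coalitions are subsampled and phi solved by the kernel-weighted linear
regression with the efficiency constraint.  Global importance is the mean
|phi| per feature over the explained instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShapConfig",
    "ShapReport",
    "kernel_shap_values",
    "explain_instances",
    "global_importance",
    "make_model_fn",
]

EXACT_MAX_P = 12


@dataclass
class ShapConfig:
    background_size: int = 100
    background_seed: int = 0
    coalition_samples: int | str = "auto"

    def n_samples(self, p: int) -> int:
        if self.coalition_samples == "auto":
            return min(2 * p + 2048, 2**p - 2 if p < 30 else 2 * p + 2048)
        return int(self.coalition_samples)


@dataclass
class ShapReport:
    phi: np.ndarray  # (n_instances, p)
    base_value: float
    feature_names: list[str] = field(default_factory=list)
    fx: np.ndarray | None = None  # model output per instance


def _coalition_values(
    model_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    masks: np.ndarray,
) -> np.ndarray:
    """v(S) for each mask row: mean model output with absent features drawn
    from the background."""
    B, p = background.shape
    out = np.empty(masks.shape[0])
    for i, mask in enumerate(masks):
        rows = np.where(mask, instance, background)  # (B, p)
        vals = np.asarray(model_fn(rows), dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("model returned a non-finite output on a coalition")
        out[i] = vals.mean()
    return out


def _exact_shap(
    model_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by full coalition enumeration (p <= 12)."""
    p = instance.size
    n_masks = 1 << p
    bits = ((np.arange(n_masks)[:, None] >> np.arange(p)) & 1).astype(bool)
    v = _coalition_values(model_fn, background, instance, bits)
    sizes = bits.sum(axis=1)
    import math as _math

    # marginal-contribution weights |S|! (p-|S|-1)! / p!
    w = np.array([_math.factorial(s) * _math.factorial(p - s - 1) / _math.factorial(p) for s in range(p)])
    phi = np.zeros(p)
    for i in range(p):
        without = ~bits[:, i]
        masks_wo = np.flatnonzero(without)
        v_wo = v[masks_wo]
        v_wi = v[masks_wo | (1 << i)]
        phi[i] = float(np.sum(w[sizes[masks_wo]] * (v_wi - v_wo)))
    return phi, float(v[0])


def _sampled_shap(
    model_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    n_samples: int,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Kernel SHAP: weighted least squares over sampled coalitions with the
    efficiency constraint sum(phi) = f(x) - E[f]."""
    p = instance.size
    rng = np.random.default_rng(seed)
    base = float(np.mean(np.asarray(model_fn(background), dtype=float)))
    fx = float(np.asarray(model_fn(instance[None]), dtype=float)[0])

    sizes = np.arange(1, p)
    size_w = (p - 1) / (sizes * (p - sizes))
    size_prob = size_w / size_w.sum()
    n_samples = max(n_samples, 2 * p)
    half = n_samples // 2
    Z = np.zeros((2 * half, p), dtype=bool)
    for r in range(half):
        s = rng.choice(sizes, p=size_prob)
        on = rng.choice(p, size=s, replace=False)
        Z[2 * r, on] = True
        Z[2 * r + 1] = ~Z[2 * r]  # paired complement
    v = _coalition_values(model_fn, background, instance, Z)
    k = Z.sum(axis=1)
    w = np.array([(p - 1) / (comb(p, int(s)) * s * (p - s)) for s in k])

    # eliminate phi_p via the efficiency constraint
    y = v - base - Z[:, -1] * (fx - base)
    A = Z[:, :-1].astype(float) - Z[:, [-1]].astype(float)
    WA = A * w[:, None]
    G = A.T @ WA + 1e-10 * np.eye(p - 1)
    phi_rest = np.linalg.solve(G, WA.T @ y)
    phi = np.empty(p)
    phi[:-1] = phi_rest
    phi[-1] = (fx - base) - phi_rest.sum()
    return phi, base


def kernel_shap_values(
    model_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instance: np.ndarray,
    config: ShapConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Shapley values and base value (mean background output) for one row.

    ``model_fn`` maps an ``(m, p)`` feature matrix to ``m`` scores and must
    be pure.  Exact enumeration when p <= 12, otherwise seeded coalition
    sampling with the kernel regression estimator.
    """
    config = config or ShapConfig()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    instance = np.asarray(instance, dtype=float).ravel()
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if background.shape[1] != instance.size:
        raise ValueError("background and instance widths differ")
    p = instance.size
    if p <= EXACT_MAX_P:
        return _exact_shap(model_fn, background, instance)
    return _sampled_shap(model_fn, background, instance, config.n_samples(p), config.background_seed)


def explain_instances(
    model_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instances: np.ndarray,
    config: ShapConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> ShapReport:
    """Shapley values for each row of ``instances`` against one background."""
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    phis = np.empty_like(instances)
    base = 0.0
    for i, row in enumerate(instances):
        phis[i], base = kernel_shap_values(model_fn, background, row, config)
    fx = np.asarray(model_fn(instances), dtype=float)
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(instances.shape[1])]
    return ShapReport(phi=phis, base_value=base, feature_names=names, fx=fx)


def global_importance(report: ShapReport) -> pd.DataFrame:
    """Mean |phi| per feature over all explained instances, descending;
    ties keep column order."""
    if report.phi.shape[0] < 1:
        raise ValueError("need at least one explained instance")
    imp = np.abs(report.phi).mean(axis=0)
    df = pd.DataFrame(
        {
            "feature": report.feature_names,
            "mean_abs_shap": imp,
            "column": np.arange(imp.size),
        }
    )
    df = df.sort_values(["mean_abs_shap", "column"], ascending=[False, True], kind="mergesort")
    df["importance_rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="column").reset_index(drop=True)


def make_model_fn(trained, concentration: float) -> Callable[[np.ndarray], np.ndarray]:
    """Bind a trained model to a fixed dose: raw feature rows -> scores.

    The concentration input is held fixed at the given value during
    explanation, so attributions are over descriptors only.
    """
    from .deepmodel import predict_scores

    def fn(rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(rows)
        return predict_scores(trained, rows, np.full(rows.shape[0], concentration))

    return fn


def sample_background(
    X_train: np.ndarray, config: ShapConfig | None = None
) -> np.ndarray:
    """Draw the background rows (default 100) from the training matrix only."""
    config = config or ShapConfig()
    n = X_train.shape[0]
    size = min(config.background_size, n)
    rng = np.random.default_rng(config.background_seed)
    return X_train[rng.choice(n, size=size, replace=False)]
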