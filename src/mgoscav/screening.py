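"""Virtual screening: score candidate compounds over a dose grid, rank
them, and call activity at a score cutoff.

Ranking is over (compound, concentration) pairs — rank 1 is the single
highest predicted score anywhere on the grid — with a per-compound best
summary as the secondary view.  The default dose grid is 100/400/500/1000
µM and the default activity cutoff is a score of -0.186 (strictly greater
counts as active); both are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assaydata import DescriptorTable
from .deepmodel import TrainedModel, predict_scores

__all__ = [
    "ScreeningResult",
    "screen_compounds",
    "classify_active",
    "rank_candidates",
    "DEFAULT_SCREEN_GRID",
    "DEFAULT_CUTOFF",
]

DEFAULT_SCREEN_GRID = (100.0, 400.0, 500.0, 1000.0)
DEFAULT_CUTOFF = -0.186


def classify_active(scores: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Active (1) iff score is strictly greater than the cutoff."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return (scores > cutoff).astype(int)


@dataclass
class ScreeningResult:
    rows: pd.DataFrame  # compound_id, concentration_uM, score, rank, active
    per_compound_best: pd.DataFrame  # compound_id, best_concentration_uM, best_score
    cutoff_used: float
    concentration_grid: tuple[float, ...]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def screen_compounds(
    model: TrainedModel,
    compounds: DescriptorTable,
    grid: Sequence[float] = DEFAULT_SCREEN_GRID,
    cutoff: float = DEFAULT_CUTOFF,
) -> ScreeningResult:
    """Predict a score for every (compound, concentration) pair and rank.

    Rank 1 is the highest score; ties break lexicographically by
    (compound_id, concentration).  Unknown feature columns fail before any
    prediction.
    """
    grid = tuple(float(g) for g in grid)
    if len(grid) == 0:
        raise ValueError("empty concentration grid")
    n, k = compounds.n_compounds, len(grid)
    feat = np.repeat(compounds.values, k, axis=0)
    conc = np.tile(np.array(grid), n)
    ids = np.repeat(np.array(compounds.compound_ids, dtype=object), k)
    if list(compounds.feature_names) != list(model.normalization.feature_names):
        raise ValueError("screening table columns do not match the model's NormalizationState")
    scores = predict_scores(model, feat, conc, feature_names=compounds.feature_names)

    df = pd.DataFrame({"compound_id": ids, "concentration_uM": conc, "score": scores})
    df = df.sort_values(
        by=["score", "compound_id", "concentration_uM"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["active"] = classify_active(df["score"].to_numpy(), cutoff)

    best = (
        df.sort_values(["score", "concentration_uM"], ascending=[False, True], kind="mergesort")
        .groupby("compound_id", sort=True)
        .first()
        .reset_index()
        .rename(columns={"concentration_uM": "best_concentration_uM", "score": "best_score"})
        [["compound_id", "best_concentration_uM", "best_score"]]
        .sort_values("best_score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return ScreeningResult(
        rows=df[["compound_id", "concentration_uM", "score", "rank", "active"]],
        per_compound_best=best,
        cutoff_used=float(cutoff),
        concentration_grid=grid,
    )


def rank_candidates(result: ScreeningResult, top_k: int) -> pd.DataFrame:
    """The top_k rows by rank; asking for more than exists returns all."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(result.rows) == 0:
        raise ValueError("empty screening result")
    if top_k > len(result.rows):
        warnings.warn(f"top_k={top_k} exceeds {len(result.rows)} rows; returning all")
        top_k = len(result.rows)
    return result.rows.nsmallest(top_k, "rank").reset_index(drop=True)
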