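"""Descriptor and assay table IO, normalization, and dataset splitting.

The modelling pipeline consumes two tables: a *descriptor table* (one row
per compound, columns are named molecular descriptors, mixed binary and
continuous) and an *assay table* of ``(compound_id, concentration_uM,
activity)`` measurements.  Descriptors are min-max scaled and raw
activities Z-scored into the "MGO scavenging activity score"; both sets of
statistics are fit on the training records only and carried around as a
:class:`NormalizationState` so exactly the same transform is applied to
validation, test and screening compounds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "AssayRecord",
    "AssayTable",
    "NormalizationState",
    "DatasetSplit",
    "ModelArrays",
    "read_descriptor_table",
    "read_assay_table",
    "fit_normalization",
    "apply_normalization",
    "invert_activity",
    "make_split",
    "build_arrays",
]


class DataValidationError(ValueError):
    """A table violated one of the input contracts."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DescriptorTable:
    """Compounds x named molecular descriptors.

    ``values`` is an ``(n_compounds, p)`` float matrix; binary descriptors
    are simply columns restricted to {0, 1}.  ``qc_log`` records every
    imputed cell and each constant column found at read time.
    """

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: str = ""
    qc_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise DataValidationError("duplicate compound ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataValidationError("duplicate feature names")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.feature_names)):
            raise DataValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.feature_names)} features"
            )
        if np.isnan(self.values).any():
            raise DataValidationError("missing values after imputation")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def row_index(self) -> dict[str, int]:
        return {cid: i for i, cid in enumerate(self.compound_ids)}

    def rows_for(self, compound_ids: Sequence[str]) -> np.ndarray:
        idx = self.row_index()
        try:
            rows = [idx[c] for c in compound_ids]
        except KeyError as exc:  # pragma: no cover - message carries the id
            raise DataValidationError(f"unknown compound id {exc.args[0]!r}") from None
        return self.values[rows]


@dataclass
class AssayRecord:
    compound_id: str
    concentration: float  # µM, strictly positive
    activity_raw: float
    activity_score: float | None = None  # Z-scale, absent until normalization


@dataclass
class AssayTable:
    records: list[AssayRecord]

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def concentration_range(self) -> tuple[float, float]:
        conc = [r.concentration for r in self.records]
        return (min(conc), max(conc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "concentration_uM": [r.concentration for r in self.records],
                "activity": [r.activity_raw for r in self.records],
            }
        )

    def check_resolves(self, descriptors: DescriptorTable) -> None:
        known = set(descriptors.compound_ids)
        missing = sorted({r.compound_id for r in self.records} - known)
        if missing:
            raise DataValidationError(
                f"{len(missing)} assay compound id(s) absent from descriptor table, "
                f"first: {missing[0]!r}"
            )


@dataclass
class NormalizationState:
    """Training-set statistics: per-feature min/max and activity mean/SD.

    The activity SD uses the sample convention (denominator ``n - 1``).
    Constant features (min == max) normalize to 0 by convention so the
    feature count stays fixed.
    """

    feature_names: list[str]
    feature_min: np.ndarray
    feature_max: np.ndarray
    activity_mean: float
    activity_sd: float
    fit_on: str = ""

    def __post_init__(self) -> None:
        self.feature_min = np.asarray(self.feature_min, dtype=float)
        self.feature_max = np.asarray(self.feature_max, dtype=float)
        if np.any(self.feature_max < self.feature_min):
            raise DataValidationError("feature_max < feature_min")
        if not self.activity_sd > 0:
            raise DataValidationError("degenerate target: activity SD must be > 0")

    def transform_features(self, values: np.ndarray) -> np.ndarray:
        """Min-max scale; out-of-range values are NOT clipped."""
        values = np.asarray(values, dtype=float)
        span = self.feature_max - self.feature_min
        out = np.zeros_like(values)
        ok = span > 0
        out[..., ok] = (values[..., ok] - self.feature_min[ok]) / span[ok]
        return out

    def transform_activity(self, raw: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(raw, dtype=float) - self.activity_mean) / self.activity_sd

    def invert_activity(self, score: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(score, dtype=float) * self.activity_sd + self.activity_mean

    # JSON round trip -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "feature_names": self.feature_names,
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "activity_mean": self.activity_mean,
            "activity_sd": self.activity_sd,
            "fit_on": self.fit_on,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationState":
        obj = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(obj["feature_names"]),
            feature_min=np.array(obj["feature_min"], dtype=float),
            feature_max=np.array(obj["feature_max"], dtype=float),
            activity_mean=float(obj["activity_mean"]),
            activity_sd=float(obj["activity_sd"]),
            fit_on=obj.get("fit_on", ""),
        )

    @classmethod
    def from_dict(cls, obj: dict) -> "NormalizationState":
        return cls(
            feature_names=list(obj["feature_names"]),
            feature_min=np.array(obj["feature_min"], dtype=float),
            feature_max=np.array(obj["feature_max"], dtype=float),
            activity_mean=float(obj["activity_mean"]),
            activity_sd=float(obj["activity_sd"]),
            fit_on=obj.get("fit_on", ""),
        )

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "activity_mean": self.activity_mean,
            "activity_sd": self.activity_sd,
            "fit_on": self.fit_on,
        }


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test record indices at an 8:1:1 ratio."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratio: tuple[int, int, int] = (8, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        n = all_idx.size
        if len(np.unique(all_idx)) != n or set(all_idx.tolist()) != set(range(n)):
            raise DataValidationError("split is not a partition of 0..n-1")

    @property
    def n(self) -> int:
        return self.train_idx.size + self.val_idx.size + self.test_idx.size

    def to_json(self, path: str | Path) -> None:
        obj = {
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "ratio": list(self.ratio),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        obj = json.loads(Path(path).read_text())
        return cls(
            train_idx=np.array(obj["train_idx"], dtype=int),
            val_idx=np.array(obj["val_idx"], dtype=int),
            test_idx=np.array(obj["test_idx"], dtype=int),
            ratio=tuple(obj["ratio"]),
            seed=int(obj["seed"]),
        )


# ---------------------------------------------------------------------------
# readers


def read_descriptor_table(
    path: str | Path,
    dialect: str = "padel_csv",
    id_column: str | None = None,
    provenance: str | None = None,
) -> DescriptorTable:
    """Read a descriptor CSV (PaDEL-style: header row, first column "Name").

    Missing cells are imputed with the column median of the present values;
    each imputation and every constant column is appended to the returned
    table's ``qc_log``.  Duplicate compound names and non-numeric cells are
    hard errors.
    """
    path = Path(path)
    if dialect not in ("padel_csv", "plain_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataValidationError("descriptor table needs an id column plus >= 1 descriptor")
    id_col = id_column if id_column is not None else df.columns[0]
    if id_col not in df.columns:
        raise DataValidationError(f"id column {id_col!r} not in header")
    names = df[id_col].astype(str).tolist()
    if len(set(names)) != len(names):
        dupes = df[id_col][df[id_col].duplicated()].tolist()
        raise DataValidationError(f"duplicate compound name(s): {dupes[:5]}")
    feat = df.drop(columns=[id_col])

    values = np.empty(feat.shape, dtype=float)
    for j, col in enumerate(feat.columns):
        numeric = pd.to_numeric(feat[col], errors="coerce")
        bad = numeric.isna() & feat[col].notna() & (feat[col].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"non-numeric cell at row {names[i]!r}, column {col!r}: {feat[col].iloc[i]!r}"
            )
        values[:, j] = numeric.to_numpy(dtype=float)

    qc_log: list[dict] = []
    for j, col in enumerate(feat.columns):
        missing = np.flatnonzero(np.isnan(values[:, j]))
        if missing.size:
            present = values[~np.isnan(values[:, j]), j]
            if present.size == 0:
                raise DataValidationError(f"column {col!r} is entirely missing")
            med = float(np.median(present))
            for i in missing:
                qc_log.append(
                    {"event": "imputed", "compound": names[int(i)], "feature": str(col), "value": med}
                )
            values[missing, j] = med
    for j, col in enumerate(feat.columns):
        if np.all(values[:, j] == values[0, j]):
            qc_log.append({"event": "constant_column", "feature": str(col), "value": float(values[0, j])})

    return DescriptorTable(
        compound_ids=names,
        feature_names=[str(c) for c in feat.columns],
        values=values,
        provenance=provenance if provenance is not None else str(path),
        qc_log=qc_log,
    )


def read_assay_table(path: str | Path, descriptors: DescriptorTable | None = None) -> AssayTable:
    """Read an assay CSV with columns compound_id, concentration_uM, activity."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"compound_id", "concentration_uM", "activity"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"assay table must have columns {sorted(required)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        conc = float(row.concentration_uM)
        if not conc > 0:
            raise DataValidationError(f"row {i}: concentration must be > 0 µM, got {conc}")
        act = float(row.activity)
        if not math.isfinite(act):
            raise DataValidationError(f"row {i}: non-finite activity")
        records.append(AssayRecord(str(row.compound_id), conc, act))
    table = AssayTable(records=records)
    if descriptors is not None:
        table.check_resolves(descriptors)
    return table


# ---------------------------------------------------------------------------
# normalization


def fit_normalization(
    descriptors: DescriptorTable,
    assays: AssayTable,
    train_idx: Sequence[int],
) -> NormalizationState:
    """Fit min-max feature ranges and activity mean/SD on training records only.

    Feature ranges come from the descriptor rows of the compounds that appear
    in training records; the activity mean and sample SD (ddof=1) come from
    the training activities themselves.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    if train_idx.size == 0:
        raise DataValidationError("empty training index set")
    assays.check_resolves(descriptors)
    train_records = [assays.records[i] for i in train_idx]
    train_compounds = sorted({r.compound_id for r in train_records})
    X = descriptors.rows_for(train_compounds)
    y = np.array([r.activity_raw for r in train_records], dtype=float)
    if np.unique(y).size < 2:
        raise DataValidationError("degenerate target: < 2 distinct training activities")
    sd = float(np.std(y, ddof=1))
    if not sd > 0:
        raise DataValidationError("degenerate target: activity SD is 0")
    return NormalizationState(
        feature_names=list(descriptors.feature_names),
        feature_min=X.min(axis=0),
        feature_max=X.max(axis=0),
        activity_mean=float(np.mean(y)),
        activity_sd=sd,
        fit_on=f"{train_idx.size} training records",
    )


@dataclass
class ModelArrays:
    """Record-aligned model-ready arrays: features, concentration, score."""

    X: np.ndarray  # (n_records, p) min-max scaled descriptors
    concentration: np.ndarray  # (n_records,) raw µM
    y: np.ndarray  # (n_records,) Z-scaled activity score
    compound_ids: list[str]

    @property
    def n(self) -> int:
        return self.y.size


def apply_normalization(
    state: NormalizationState,
    descriptors: DescriptorTable,
    assays: AssayTable,
) -> ModelArrays:
    """Map every assay record to (scaled features, concentration, score)."""
    if list(descriptors.feature_names) != list(state.feature_names):
        raise DataValidationError("feature names do not match the fitted NormalizationState")
    assays.check_resolves(descriptors)
    ids = assays.compound_ids
    X = state.transform_features(descriptors.rows_for(ids))
    conc = np.array([r.concentration for r in assays.records], dtype=float)
    raw = np.array([r.activity_raw for r in assays.records], dtype=float)
    y = np.asarray(state.transform_activity(raw))
    for rec, score in zip(assays.records, y):
        rec.activity_score = float(score)
    return ModelArrays(X=X, concentration=conc, y=y, compound_ids=list(ids))


def build_arrays(descriptors: DescriptorTable, assays: AssayTable) -> ModelArrays:
    """Record-aligned raw arrays (no scaling); convenience for baselines."""
    ids = assays.compound_ids
    assays.check_resolves(descriptors)
    return ModelArrays(
        X=descriptors.rows_for(ids),
        concentration=np.array([r.concentration for r in assays.records], dtype=float),
        y=np.array([r.activity_raw for r in assays.records], dtype=float),
        compound_ids=list(ids),
    )


def invert_activity(state: NormalizationState, scores: np.ndarray) -> np.ndarray:
    return np.asarray(state.invert_activity(scores))


# ---------------------------------------------------------------------------
# splitting


def make_split(
    n_records: int,
    ratio: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
    groups: Sequence[str] | None = None,
) -> DatasetSplit:
    """Shuffle records and split 8:1:1 (val = test = floor(n/10), train = rest).

    Splitting is by assay record; the same compound measured at several
    concentrations can therefore land in different folds.  Passing
    ``groups`` (one label per record, e.g. compound ids) switches to a
    grouped split where whole groups are assigned to folds until the fold
    quotas are reached.
    """
    if ratio != (8, 1, 1):
        raise ValueError("only the 8:1:1 ratio is supported")
    if n_records < 10:
        raise DataValidationError(f"need >= 10 records to split 8:1:1, got {n_records}")
    rng = np.random.default_rng(seed)
    n_val = n_records // 10
    n_test = n_records // 10
    if groups is None:
        perm = rng.permutation(n_records)
        val = np.sort(perm[:n_val])
        test = np.sort(perm[n_val : n_val + n_test])
        train = np.sort(perm[n_val + n_test :])
    else:
        if len(groups) != n_records:
            raise DataValidationError("groups length must equal n_records")
        uniq = list(dict.fromkeys(groups))
        order = rng.permutation(len(uniq))
        members: dict[str, list[int]] = {}
        for i, g in enumerate(groups):
            members.setdefault(g, []).append(i)
        val_l: list[int] = []
        test_l: list[int] = []
        train_l: list[int] = []
        for gi in order:
            g = uniq[gi]
            if len(val_l) + len(members[g]) <= n_val:
                val_l.extend(members[g])
            elif len(test_l) + len(members[g]) <= n_test:
                test_l.extend(members[g])
            else:
                train_l.extend(members[g])
        if not val_l or not test_l:
            warnings.warn("grouped split left an empty fold; group sizes exceed fold quota")
        val, test, train = (np.sort(np.array(s, dtype=int)) for s in (val_l, test_l, train_l))
    return DatasetSplit(train_idx=train, val_idx=val, test_idx=test, ratio=ratio, seed=seed)
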