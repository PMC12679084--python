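"""Synthetic descriptor/assay/label generator with known ground truth.

Emulates the statistical structure the pipeline assumes: a sparse set of
informative descriptors drives a latent scavenging potency in [0, 1]
through a logistic link; measured activity follows a monotone Hill
dose-response in concentration with additive Gaussian noise.  Defaults
reproduce the in-house data shape (660 compounds, 2,262 records, doses
within 0.001-1,000 µM) at a descriptor width of 200.

EC50 is tied deterministically to potency (stronger scavengers bind at
lower dose), so activity is a learnable function of descriptors and
concentration up to the noise floor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assaydata import AssayRecord, AssayTable, DescriptorTable

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_compounds",
    "generate_assays",
    "generate_labeled_set",
    "generate_emulation_dataset",
    "write_descriptor_csv",
    "write_assay_csv",
]

#: concentration grid used when sampling assay records (µM); spans the
#: assay's working range and includes the 400 µM screening dose.
DEFAULT_GRID = (0.1, 1.0, 10.0, 100.0, 400.0, 1000.0)


@dataclass
class SynthConfig:
    n_compounds: int = 660
    p_binary: int = 160
    p_continuous: int = 40
    k_informative: int = 20
    weight_scale: float = 2.0
    hill_coefficient: float = 1.0
    ec50_log10_range: tuple[float, float] = (0.0, 2.5)  # 1-316 µM
    noise_sd: float = 0.05
    concentration_grid: tuple[float, ...] = DEFAULT_GRID
    records_total: int | None = 2262
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.p_binary + self.p_continuous:
            raise ValueError("k_informative exceeds total feature count")
        if not self.hill_coefficient > 0:
            raise ValueError("hill_coefficient must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in self.concentration_grid:
            if not (0.001 <= c <= 1000.0):
                raise ValueError(f"grid concentration {c} outside 0.001-1000 µM")

    @property
    def p(self) -> int:
        return self.p_binary + self.p_continuous

    def child_seed(self, stage: int) -> np.random.SeedSequence:
        # one global seed fans out to per-stage children so each stage is
        # independently reproducible
        return np.random.SeedSequence(self.seed).spawn(stage + 1)[stage]


@dataclass
class GroundTruth:
    informative_idx: np.ndarray
    weights: np.ndarray  # dense over informative_idx order
    potency: np.ndarray  # per compound, in [0, 1]
    ec50: np.ndarray  # per compound, µM
    compound_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "informative_idx": self.informative_idx.tolist(),
            "weights": self.weights.tolist(),
            "potency": self.potency.tolist(),
            "ec50": self.ec50.tolist(),
            "compound_ids": self.compound_ids,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            informative_idx=np.array(obj["informative_idx"], dtype=int),
            weights=np.array(obj["weights"], dtype=float),
            potency=np.array(obj["potency"], dtype=float),
            ec50=np.array(obj["ec50"], dtype=float),
            compound_ids=list(obj["compound_ids"]),
        )


def generate_compounds(config: SynthConfig) -> tuple[DescriptorTable, GroundTruth]:
    """Draw a descriptor table and its latent ground truth.

    Binary descriptors ~ Bernoulli(0.2), continuous ~ N(0, 1).  A sparse
    weight vector on ``k_informative`` randomly placed features yields the
    latent signal, standardized to unit scale before the logistic link so
    ``weight_scale`` controls the potency spread directly.
    """
    rng = np.random.default_rng(config.child_seed(0))
    n, pb, pc = config.n_compounds, config.p_binary, config.p_continuous
    B = rng.binomial(1, 0.2, size=(n, pb)).astype(float)
    C = rng.standard_normal(size=(n, pc))
    X = np.concatenate([B, C], axis=1)
    feature_names = [f"FP{j:04d}" for j in range(pb)] + [f"D{j:04d}" for j in range(pc)]
    compound_ids = [f"CMPD{i:04d}" for i in range(n)]

    informative = np.sort(rng.choice(config.p, size=config.k_informative, replace=False))
    # weights are specified on the standardized feature scale (magnitude
    # U(0.5, 1.5), random sign) so binary and continuous informative
    # features contribute comparable signal; the applied weight is u/sd.
    u = rng.uniform(0.5, 1.5, config.k_informative) * rng.choice([-1.0, 1.0], config.k_informative)
    sd = np.where(informative < pb, math.sqrt(0.2 * 0.8), 1.0)
    mean = np.where(informative < pb, 0.2, 0.0)
    w = u / sd
    z = (X[:, informative] - mean) @ w / np.linalg.norm(u)
    potency = 1.0 / (1.0 + np.exp(-config.weight_scale * z))

    lo, hi = config.ec50_log10_range
    ec50 = 10.0 ** (hi - potency * (hi - lo))  # potent compounds act at lower dose

    table = DescriptorTable(
        compound_ids=compound_ids,
        feature_names=feature_names,
        values=X,
        provenance=f"synthetic seed={config.seed}",
    )
    truth = GroundTruth(
        informative_idx=informative,
        weights=w,
        potency=potency,
        ec50=ec50,
        compound_ids=compound_ids,
    )
    return table, truth


def hill_response(conc: np.ndarray, potency: np.ndarray, ec50: np.ndarray, h: float) -> np.ndarray:
    """Noise-free activity: potency * c^h / (c^h + EC50^h)."""
    c = np.asarray(conc, dtype=float)
    return potency * c**h / (c**h + ec50**h)


def generate_assays(
    compounds: DescriptorTable, truth: GroundTruth, config: SynthConfig
) -> AssayTable:
    """Sample assay records over the concentration grid.

    Each compound receives at least one record; when ``records_total`` is
    set the remaining records are spread uniformly at random so the table
    size is exact.  Replicate (compound, concentration) pairs are allowed.
    """
    if len(config.concentration_grid) == 0:
        raise ValueError("empty concentration grid")
    rng = np.random.default_rng(config.child_seed(1))
    n = compounds.n_compounds
    grid = np.asarray(config.concentration_grid, dtype=float)
    if config.records_total is None:
        counts = np.full(n, len(grid), dtype=int)
    else:
        if config.records_total < n:
            raise ValueError("records_total smaller than n_compounds")
        counts = np.ones(n, dtype=int)
        extra = rng.choice(n, size=config.records_total - n, replace=True)
        np.add.at(counts, extra, 1)
    records: list[AssayRecord] = []
    for i, cid in enumerate(compounds.compound_ids):
        if config.records_total is None:
            conc = grid.copy()  # the full dose ladder, once each
        else:
            conc = rng.choice(grid, size=counts[i], replace=True)
        clean = hill_response(conc, truth.potency[i], truth.ec50[i], config.hill_coefficient)
        noisy = clean + rng.normal(0.0, config.noise_sd, size=counts[i]) if config.noise_sd > 0 else clean
        for c, a in zip(conc, np.atleast_1d(noisy)):
            records.append(AssayRecord(cid, float(c), float(a)))
    return AssayTable(records=records)


def generate_labeled_set(
    compounds: DescriptorTable, truth: GroundTruth, threshold: float
) -> pd.DataFrame:
    """Binary active/inactive labels from a potency cutoff.

    ``active = 1`` iff latent potency >= threshold.  Emits a warning flag
    column-wise caller-visible via ``attrs['single_class']`` when only one
    class is produced (ROC undefined downstream).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    active = (truth.potency >= threshold).astype(int)
    df = pd.DataFrame({"compound_id": compounds.compound_ids, "active": active})
    df.attrs["n_active"] = int(active.sum())
    df.attrs["n_inactive"] = int((1 - active).sum())
    df.attrs["single_class"] = bool(active.min() == active.max())
    return df


def potency_from_features(
    X: np.ndarray, truth: GroundTruth, config: SynthConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Latent potency and EC50 for new feature rows under an existing truth."""
    idx = truth.informative_idx
    sd = np.where(idx < config.p_binary, math.sqrt(0.2 * 0.8), 1.0)
    mean = np.where(idx < config.p_binary, 0.2, 0.0)
    u = truth.weights * sd  # standardized-scale weights
    z = (X[:, idx] - mean) @ truth.weights / np.linalg.norm(u)
    potency = 1.0 / (1.0 + np.exp(-config.weight_scale * z))
    lo, hi = config.ec50_log10_range
    ec50 = 10.0 ** (hi - potency * (hi - lo))
    return potency, ec50


def generate_unseen_compounds(
    truth: GroundTruth,
    config: SynthConfig,
    seed: int,
    n_compounds: int | None = None,
    prefix: str = "NEW",
) -> tuple[DescriptorTable, GroundTruth]:
    """Fresh compounds governed by the *same* structure-activity truth.

    Draws new descriptor rows from the feature distribution and scores
    them with the existing informative weights — screening candidates the
    model has never seen, but whose true potencies live on the learned
    landscape.
    """
    n = n_compounds if n_compounds is not None else config.n_compounds
    rng = np.random.default_rng(seed)
    B = rng.binomial(1, 0.2, size=(n, config.p_binary)).astype(float)
    C = rng.standard_normal(size=(n, config.p_continuous))
    X = np.concatenate([B, C], axis=1)
    potency, ec50 = potency_from_features(X, truth, config)
    feature_names = [f"FP{j:04d}" for j in range(config.p_binary)] + [
        f"D{j:04d}" for j in range(config.p_continuous)
    ]
    table = DescriptorTable(
        compound_ids=[f"{prefix}{i:04d}" for i in range(n)],
        feature_names=feature_names,
        values=X,
        provenance=f"synthetic unseen seed={seed}",
    )
    new_truth = GroundTruth(
        informative_idx=truth.informative_idx.copy(),
        weights=truth.weights.copy(),
        potency=potency,
        ec50=ec50,
        compound_ids=list(table.compound_ids),
    )
    return table, new_truth


def screening_panel(
    compounds: DescriptorTable,
    truth: GroundTruth,
    n_panel: int = 12,
    top_potency: float = 0.99,
) -> tuple[DescriptorTable, np.ndarray]:
    """A screening panel with a distinctly strongest candidate.

    Picks ``n_panel - 1`` compounds nearest to evenly spaced potency
    targets in the weak-to-moderate range plus one compound near
    ``top_potency``, emulating an application set in which the best
    scavenger clearly stands out.  The potency gap between the top
    candidate and the rest is then larger than any regressor's ordering
    resolution, which is what makes a rank-1 check meaningful.  Returns the
    panel table and the selected row indices (ascending potency target,
    last = most potent).
    """
    targets = np.append(np.linspace(0.05, 0.70, n_panel - 1), top_potency)
    pick: list[int] = []
    for t in targets:
        dist = np.abs(truth.potency - t)
        dist[pick] = np.inf  # without replacement
        pick.append(int(np.argmin(dist)))
    pick = np.array(pick)
    panel = DescriptorTable(
        compound_ids=[compounds.compound_ids[i] for i in pick],
        feature_names=compounds.feature_names,
        values=compounds.values[pick],
        provenance="potency-spread screening panel",
    )
    return panel, pick


def generate_emulation_dataset(
    seed: int = 0, **overrides
) -> tuple[DescriptorTable, GroundTruth, AssayTable, SynthConfig]:
    """One-call generator at the emulation scale (660 compounds, 2,262 records)."""
    config = SynthConfig(seed=seed, **overrides)
    compounds, truth = generate_compounds(config)
    assays = generate_assays(compounds, truth, config)
    return compounds, truth, assays, config


# ---------------------------------------------------------------------------
# CSV writers (same dialects assaydata reads)


def write_descriptor_csv(table: DescriptorTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "Name", table.compound_ids)
    df.to_csv(path, index=False)


def write_assay_csv(assays: AssayTable, path: str | Path) -> None:
    assays.to_frame().to_csv(path, index=False)
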