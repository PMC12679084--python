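"""High-level study workflows shared by the CLI, tests and scripts.

One call takes descriptor + assay tables through the standard pipeline:
8:1:1 record split, normalization fit on the training fold only, DeepMGO
training, and test-fold regression metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import assaydata, deepmodel, metrics, synthdata
from .assaydata import AssayTable, DescriptorTable, DatasetSplit, ModelArrays, NormalizationState


def subset_arrays(arrays: ModelArrays, idx: np.ndarray) -> ModelArrays:
    return ModelArrays(
        X=arrays.X[idx],
        concentration=arrays.concentration[idx],
        y=arrays.y[idx],
        compound_ids=[arrays.compound_ids[i] for i in idx],
    )


@dataclass
class TrainingStudy:
    trained: deepmodel.TrainedModel
    split: DatasetSplit
    state: NormalizationState
    arrays: ModelArrays
    test_report: metrics.EvalReport


def train_study(
    descriptors: DescriptorTable,
    assays: AssayTable,
    seed: int,
    train_config: deepmodel.TrainConfig | None = None,
    spec: deepmodel.DeepMGOSpec | None = None,
) -> TrainingStudy:
    """Split, normalize, train DeepMGO, and evaluate on the held-out fold."""
    split = assaydata.make_split(assays.n_records, seed=seed)
    state = assaydata.fit_normalization(descriptors, assays, split.train_idx)
    arrays = assaydata.apply_normalization(state, descriptors, assays)
    config = train_config or deepmodel.TrainConfig(seed=seed)
    p = descriptors.n_features
    if spec is None:
        spec = deepmodel.compact_spec(p) if p < 800 else deepmodel.reference_spec(p)
    net = deepmodel.build_deepmgo(spec, seed=config.seed)
    trained = deepmodel.train_model(
        net,
        subset_arrays(arrays, split.train_idx),
        config,
        state,
        val=subset_arrays(arrays, split.val_idx),
    )
    test = subset_arrays(arrays, split.test_idx)
    report = metrics.regression_metrics(
        deepmodel.PredictionSet(test.y, trained.predict_normalized(test.X, test.concentration))
    )
    return TrainingStudy(trained=trained, split=split, state=state, arrays=arrays, test_report=report)


def emulation_study(
    seed: int,
    train_config: deepmodel.TrainConfig | None = None,
    **synth_overrides,
):
    """Generate the emulation-scale synthetic study and train on it."""
    compounds, truth, assays, config = synthdata.generate_emulation_dataset(
        seed=seed, **synth_overrides
    )
    study = train_study(compounds, assays, seed=seed, train_config=train_config)
    return study, compounds, truth, config
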