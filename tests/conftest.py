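"""Shared fixtures: a small synthetic study and a quickly trained model.

Everything is generated programmatically under fixed seeds; the session
scope keeps the one short training run shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from mgoscav import assaydata, deepmodel, synthdata


@pytest.fixture(scope="session")
def small_config() -> synthdata.SynthConfig:
    return synthdata.SynthConfig(
        n_compounds=60,
        p_binary=40,
        p_continuous=20,
        k_informative=6,
        records_total=240,
        noise_sd=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    compounds, truth = synthdata.generate_compounds(small_config)
    assays = synthdata.generate_assays(compounds, truth, small_config)
    return compounds, truth, assays


@pytest.fixture(scope="session")
def small_arrays(small_study):
    compounds, truth, assays = small_study
    split = assaydata.make_split(assays.n_records, seed=7)
    state = assaydata.fit_normalization(compounds, assays, split.train_idx)
    arrays = assaydata.apply_normalization(state, compounds, assays)
    return arrays, split, state


def take(arrays: assaydata.ModelArrays, idx: np.ndarray) -> assaydata.ModelArrays:
    return assaydata.ModelArrays(
        X=arrays.X[idx],
        concentration=arrays.concentration[idx],
        y=arrays.y[idx],
        compound_ids=[arrays.compound_ids[i] for i in idx],
    )


@pytest.fixture(scope="session")
def small_trained(small_study, small_arrays):
    """A briefly trained compact model on the small study (for contract
    tests of prediction, screening and explanation, not for accuracy)."""
    compounds, truth, assays = small_study
    arrays, split, state = small_arrays
    net = deepmodel.build_deepmgo(deepmodel.compact_spec(compounds.n_features), seed=7)
    config = deepmodel.TrainConfig(epochs=25, seed=7)
    trained = deepmodel.train_model(
        net, take(arrays, split.train_idx), config, state, val=take(arrays, split.val_idx)
    )
    return trained
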