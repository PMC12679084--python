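"""Conv forward pass vs brute force, parameter accounting, training
determinism, prediction contracts, checkpoint round trip."""

from __future__ import annotations

import numpy as np
import pytest

from mgoscav import assaydata, deepmodel
from mgoscav.deepmodel import (
    ConcentrationScaler,
    ConvBlockSpec,
    DeepMGOSpec,
    PredictionSet,
    TrainConfig,
    build_deepmgo,
    conv_block_forward,
    count_trainable_parameters,
    load_checkpoint,
    predict_scores,
    reference_spec,
    save_checkpoint,
    train_model,
)
from conftest import take


def brute_force_conv(x, W, b, stride):
    """Triple loop over output position j, kernel m, tap l (and channels)."""
    in_len, in_ch = x.shape
    M, L, _ = W.shape
    out_len = (in_len - L) // stride + 1
    out = np.zeros((out_len, M))
    for j in range(out_len):
        for m in range(M):
            acc = b[m]
            for l in range(L):
                for c in range(in_ch):
                    acc += W[m, l, c] * x[j * stride + l, c]
            out[j, m] = acc
    return out


class TestConvBlockForward:
    def test_identity_kernel_passes_input_through(self):
        spec = ConvBlockSpec(1, 1, 1, "identity", False,
                             weights=np.ones((1, 1, 1)), bias=np.zeros(1))
        x = np.array([[1.0], [2.0], [-3.0]])
        np.testing.assert_array_equal(conv_block_forward(x, spec), x)

    def test_hand_computed_example(self):
        # input [1,2,3], kernel [1,1], bias 0 -> [3, 5]
        spec = ConvBlockSpec(1, 2, 1, "identity", False,
                             weights=np.ones((1, 2, 1)), bias=np.zeros(1))
        out = conv_block_forward(np.array([[1.0], [2.0], [3.0]]), spec)
        np.testing.assert_array_equal(out[:, 0], [3.0, 5.0])

    def test_relu_clamps_negative_preactivation(self):
        spec = ConvBlockSpec(1, 1, 1, "relu", False,
                             weights=np.full((1, 1, 1), -2.0), bias=np.zeros(1))
        out = conv_block_forward(np.array([[1.0]]), spec)
        assert out[0, 0] == 0.0

    def test_input_shorter_than_kernel_rejected(self):
        spec = ConvBlockSpec(1, 5, 1, "identity", False,
                             weights=np.ones((1, 5, 1)), bias=np.zeros(1))
        with pytest.raises(ValueError, match="shorter"):
            conv_block_forward(np.ones((3, 1)), spec)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        in_len = int(rng.integers(5, 16))
        in_ch = int(rng.integers(1, 4))
        M = int(rng.integers(1, 5))
        L = int(rng.integers(1, min(in_len, 5) + 1))
        stride = int(rng.integers(1, 3))
        W = rng.normal(size=(M, L, in_ch))
        b = rng.normal(size=M)
        x = rng.normal(size=(in_len, in_ch))
        spec = ConvBlockSpec(M, L, stride, "identity", False, weights=W, bias=b)
        np.testing.assert_allclose(
            conv_block_forward(x, spec), brute_force_conv(x, W, b, stride), atol=1e-10
        )


def spec_param_count(spec: DeepMGOSpec) -> int:
    """Closed-form parameter sum from layer shapes (independent oracle)."""
    total, in_ch, length = 0, 1, spec.input_width
    for b in spec.conv_blocks:
        total += b.n_kernels * b.kernel_length * in_ch + b.n_kernels
        if b.batch_norm:
            total += 2 * b.n_kernels
        length = (length - b.kernel_length) // b.stride + 1
        in_ch = b.n_kernels
    total += length * in_ch * spec.feature_dense_width + spec.feature_dense_width
    total += 1 * spec.concentration_dense_width + spec.concentration_dense_width
    concat = spec.feature_dense_width + spec.concentration_dense_width
    total += concat * spec.head_widths[0] + spec.head_widths[0]
    total += spec.head_widths[0] * spec.head_widths[1] + spec.head_widths[1]
    return total


class TestArchitecture:
    def test_reference_spec_builds_scalar_output(self):
        net = build_deepmgo(reference_spec(2756), seed=0)
        out = net.forward(np.zeros((3, 2756)), np.zeros(3))
        assert out.shape == (3,)

    def test_two_conv_blocks_rejected(self):
        spec = reference_spec(500)
        spec.conv_blocks = spec.conv_blocks[:2]
        with pytest.raises(ValueError, match="3 conv"):
            build_deepmgo(spec, seed=0)

    def test_nonscalar_head_rejected(self):
        spec = reference_spec(500)
        spec.head_widths = (64, 3)
        with pytest.raises(ValueError, match="scalar"):
            build_deepmgo(spec, seed=0)

    def test_identical_seeds_identical_weights(self):
        a = build_deepmgo(reference_spec(300), seed=4)
        b = build_deepmgo(reference_spec(300), seed=4)
        for (_, va, _), (_, vb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(va, vb)

    def test_single_dense_parameter_count(self):
        # a 4-input -> 1-unit dense layer has 5 parameters
        spec = DeepMGOSpec(
            input_width=16,
            conv_blocks=[ConvBlockSpec(1, 1, 1, "identity", False)] * 3,
            feature_dense_width=1,
            concentration_dense_width=1,
            head_widths=(4, 1),
        )
        # closed-form oracle covers the dense contribution 4*1+1
        assert spec_param_count(spec) == count_trainable_parameters(build_deepmgo(spec, 0))

    def test_conv_block_with_batchnorm_count(self):
        # M=8, L=5, 1 channel, batch norm: 8*5 + 8 + 2*8 = 64
        spec = DeepMGOSpec(
            input_width=32,
            conv_blocks=[
                ConvBlockSpec(8, 5, 1, "relu", True),
                ConvBlockSpec(1, 1, 1, "identity", False),
                ConvBlockSpec(1, 1, 1, "identity", False),
            ],
            feature_dense_width=1,
            concentration_dense_width=1,
            head_widths=(1, 1),
        )
        net = build_deepmgo(spec, 0)
        conv1 = net.feature_layers[0]
        bn1 = net.feature_layers[1]
        block_params = sum(v.size for _, v, _ in conv1.params()) + sum(
            v.size for _, v, _ in bn1.params()
        )
        assert block_params == 64

    def test_reference_spec_is_0_22_million_parameters(self):
        n = count_trainable_parameters(build_deepmgo(reference_spec(2756), seed=0))
        assert round(n / 1e6, 2) == 0.22

    @pytest.mark.parametrize("seed", range(8))
    def test_count_matches_closed_form_for_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        blocks = []
        length = int(rng.integers(120, 400))
        spec = DeepMGOSpec(
            input_width=length,
            conv_blocks=[
                ConvBlockSpec(
                    int(rng.integers(1, 12)),
                    int(rng.integers(1, 6)),
                    int(rng.integers(1, 3)),
                    "relu",
                    bool(rng.integers(0, 2)),
                )
                for _ in range(3)
            ],
            feature_dense_width=int(rng.integers(1, 40)),
            concentration_dense_width=int(rng.integers(1, 10)),
            head_widths=(int(rng.integers(1, 30)), 1),
        )
        net = build_deepmgo(spec, seed=seed)
        assert count_trainable_parameters(net) == spec_param_count(spec)


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, small_study, small_arrays):
        compounds, truth, assays = small_study
        arrays, split, state = small_arrays
        net = build_deepmgo(deepmodel.compact_spec(compounds.n_features), seed=0)
        tm = train_model(net, take(arrays, split.train_idx), TrainConfig(epochs=15, seed=0), state)
        assert tm.history["train_loss"][-1] < tm.history["train_loss"][0]
        assert len(tm.history["train_loss"]) == 15
        assert np.isfinite(tm.history["train_loss"]).all()

    def test_deterministic_training_bitwise(self, small_study, small_arrays):
        compounds, truth, assays = small_study
        arrays, split, state = small_arrays
        results = []
        for _ in range(2):
            net = build_deepmgo(deepmodel.compact_spec(compounds.n_features), seed=3)
            tm = train_model(net, take(arrays, split.train_idx),
                             TrainConfig(epochs=5, seed=3), state)
            results.append({k: v.copy() for k, v, _ in tm.network.parameters()})
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])

    def test_divergence_aborts_with_diagnostic(self, small_study, small_arrays):
        compounds, truth, assays = small_study
        arrays, split, state = small_arrays
        bad = assaydata.ModelArrays(
            X=arrays.X[split.train_idx],
            concentration=arrays.concentration[split.train_idx],
            y=np.full(split.train_idx.size, np.nan),
            compound_ids=[arrays.compound_ids[i] for i in split.train_idx],
        )
        net = build_deepmgo(deepmodel.compact_spec(compounds.n_features), seed=0)
        with pytest.raises(deepmodel.TrainingDiverged, match="learning_rate"):
            train_model(net, bad, TrainConfig(epochs=2, seed=0), state)

    def test_train_config_defaults_match_reference_settings(self):
        cfg = TrainConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.learning_rate) == (200, 50, 2e-4)
        assert cfg.optimizer == "adam" and cfg.loss == "rmse"


class TestPrediction:
    def test_duplicate_rows_identical_scores_and_purity(self, small_trained, small_study):
        compounds, _, _ = small_study
        row = compounds.values[[0]]
        X = np.vstack([row, row, row])
        s = predict_scores(small_trained, X, [400.0, 400.0, 400.0])
        # identical rows agree to numerical noise within a batch...
        np.testing.assert_allclose(s, s[0], atol=1e-9)
        # ...and the function is pure: the same call repeats bitwise
        s2 = predict_scores(small_trained, X, [400.0, 400.0, 400.0])
        np.testing.assert_array_equal(s, s2)

    def test_batch_invariance(self, small_trained, small_study):
        compounds, _, _ = small_study
        X = compounds.values[:10]
        conc = np.full(10, 400.0)
        full = predict_scores(small_trained, X, conc)
        single = predict_scores(small_trained, X[[4]], [400.0])
        assert single[0] == pytest.approx(full[4], abs=1e-6)
        perm = np.array([3, 1, 4, 0, 2])
        permuted = predict_scores(small_trained, X[perm], conc[:5])
        np.testing.assert_allclose(permuted, full[perm], atol=1e-9)

    def test_feature_mismatch_rejected(self, small_trained):
        with pytest.raises(ValueError, match="width|names"):
            predict_scores(small_trained, np.zeros((2, 3)), [1.0, 1.0])

    def test_checkpoint_round_trip_bitwise(self, small_trained, small_study, tmp_path):
        compounds, _, _ = small_study
        save_checkpoint(small_trained, tmp_path / "ck")
        back = load_checkpoint(tmp_path / "ck")
        X = compounds.values[:8]
        conc = np.full(8, 100.0)
        np.testing.assert_array_equal(
            predict_scores(small_trained, X, conc), predict_scores(back, X, conc)
        )


class TestConcentrationScaler:
    def test_log10_default_maps_range_to_unit(self):
        sc = ConcentrationScaler.fit(np.array([0.001, 1000.0]))
        np.testing.assert_allclose(sc.transform(np.array([0.001, 1000.0])), [0.0, 1.0])
        assert sc.transform(np.array([1.0]))[0] == pytest.approx(0.5)

    def test_linear_mode(self):
        sc = ConcentrationScaler.fit(np.array([100.0, 500.0]), log10=False)
        assert sc.transform(np.array([300.0]))[0] == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationScaler.fit(np.array([0.0, 1.0]))
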