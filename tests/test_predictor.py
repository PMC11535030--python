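"""The contact CNN: shapes, gradients, training contracts, transfer, decoding."""

import numpy as np
import pytest

from neohic.contigs import encode_cscn
from neohic.nn import Conv1d, Dense, GatedBlock, MaxPool, ReLU, Sequential
from neohic.predictor import (
    PredictorConfig,
    PredictorState,
    TrainHyper,
    TrainSample,
    build_predictor,
    load_checkpoint,
    predict_contig_matrix,
    predict_decode,
    predict_pole,
    save_checkpoint,
    train_total,
    transfer_weights,
)


def tiny_cfg():
    """A miniature stack for fast structural tests (pool factor 8)."""
    return PredictorConfig(
        conv_units=(6, 8), conv_kernels=(5, 3), pool_widths=(4, 2),
        dilated_units=5, dilation_rates=(1, 2, 1),
        window_bp=4_000, resolution=500, dropout=0.2,
    )


@pytest.fixture(scope="module")
def scaled_state():
    return build_predictor(PredictorConfig.scaled_down(), seed=0)


class TestConfig:
    @pytest.mark.parametrize(
        "cfg,expected",
        [
            (PredictorConfig(), 25),
            (PredictorConfig.two_megabase(), 49),
            (PredictorConfig.ten_kb(), 101),
        ],
    )
    def test_pole_lengths(self, cfg, expected):
        assert cfg.pole_length == expected

    def test_inconsistent_stack_rejected(self):
        with pytest.raises(ValueError):
            PredictorConfig(conv_units=(10, 20), conv_kernels=(8,), pool_widths=(4, 5))

    def test_window_must_survive_pooling(self):
        with pytest.raises(ValueError):
            PredictorConfig(window_bp=1_000_500, resolution=500)


class TestGradients:
    def test_conv_forward_matches_direct_convolution(self, rng):
        conv = Conv1d(2, 3, 3, dilation=2, rng=rng)
        x = rng.normal(size=(9, 2)).astype(np.float32)  # (length, channels)
        y, _ = conv.forward(x)
        # direct oracle
        xp = np.pad(x, ((conv.pad_left, conv.pad_right), (0, 0)))
        for o in range(3):
            for l in range(9):
                expect = conv.b.value[o] + sum(
                    conv.w.value[t, c, o] * xp[l + t * 2, c] for t in range(3) for c in range(2)
                )
                assert y[l, o] == pytest.approx(expect, rel=1e-5)

    @pytest.mark.parametrize("layer_fn", [
        lambda rng: Conv1d(3, 4, 3, rng=rng),
        lambda rng: Conv1d(3, 4, 4, dilation=2, rng=rng),
        lambda rng: GatedBlock(3, 3, 2, rng),
        lambda rng: Sequential([Conv1d(3, 4, 3, rng=rng), ReLU(), MaxPool(2), Dense(4 * 6, 5, rng)]),
    ])
    def test_backward_matches_directional_derivative(self, rng, layer_fn):
        layer = layer_fn(rng)
        x = rng.normal(size=(12, 3)).astype(np.float32)  # (length, channels)
        y, cache = layer.forward(x)
        g = rng.normal(size=y.shape).astype(np.float32)  # d(loss)/dy
        dx = layer.backward(cache, g)
        v = rng.normal(size=x.shape).astype(np.float32)
        eps = 1e-2
        yp, _ = layer.forward((x + eps * v).astype(np.float32))
        ym, _ = layer.forward((x - eps * v).astype(np.float32))
        numeric = float(np.sum(g * (yp - ym)) / (2 * eps))
        analytic = float(np.sum(dx * v))
        assert numeric == pytest.approx(analytic, rel=5e-2, abs=1e-2)

    def test_parameter_gradient_matches_finite_difference(self, rng):
        layer = Conv1d(2, 2, 3, rng=rng)
        x = rng.normal(size=(10, 2)).astype(np.float32)
        y, cache = layer.forward(x)
        g = rng.normal(size=y.shape).astype(np.float32)
        layer.w.grad[...] = 0
        layer.backward(cache, g)
        analytic = layer.w.grad.copy()
        eps = 1e-2
        idx = (1, 0, 1)
        layer.w.value[idx] += eps
        yp, _ = layer.forward(x)
        layer.w.value[idx] -= 2 * eps
        ym, _ = layer.forward(x)
        layer.w.value[idx] += eps
        numeric = float(np.sum(g * (yp - ym)) / (2 * eps))
        assert numeric == pytest.approx(float(analytic[idx]), rel=5e-2, abs=1e-2)


class TestPrediction:
    def test_scaled_config_runs_and_outputs_25(self, scaled_state):
        x = encode_cscn("ACGT" * 26_000, 1)
        y = predict_pole(scaled_state, x)
        assert y.shape == (25,)
        assert (y >= 0).all()

    def test_inference_deterministic(self, scaled_state, rng):
        x = encode_cscn("".join(rng.choice(list("ACGT"), 104_000)), 1)
        a = predict_pole(scaled_state, x)
        b = predict_pole(scaled_state, x)
        assert np.array_equal(a, b)

    def test_wrong_width_rejected(self, scaled_state):
        with pytest.raises(ValueError):
            predict_pole(scaled_state, encode_cscn("ACGT", 1))

    def test_strand_average_equals_mean_of_branches(self, scaled_state, rng):
        x = encode_cscn("".join(rng.choice(list("ACGT"), 104_000)), 1)
        avg = predict_pole(scaled_state, x, strand_average=True)
        f = predict_pole(scaled_state, x)
        r = predict_pole(scaled_state, x[::-1, ::-1].copy())
        assert np.allclose(avg, (f + r) / 2)

    def test_cscn_mu_changes_encoding_mode_output(self, scaled_state, rng):
        seq = "".join(rng.choice(list("ACGT"), 104_000))
        y1 = predict_pole(scaled_state, encode_cscn(seq, 1))
        y2 = predict_pole(scaled_state, encode_cscn(seq, 2))
        assert not np.allclose(y1, y2)

    def test_decode_is_exactly_linear_in_mu(self, scaled_state, rng):
        seq = "".join(rng.choice(list("ACGT"), 104_000))
        onehot = encode_cscn(seq, 1)
        y1 = predict_decode(scaled_state, onehot, 1)
        y3 = predict_decode(scaled_state, onehot, 3)
        assert np.allclose(y3, 3 * y1)
        assert np.array_equal(y1, predict_pole(scaled_state, onehot))

    def test_decode_rejects_bad_inputs(self, scaled_state, rng):
        seq = "".join(rng.choice(list("ACGT"), 104_000))
        with pytest.raises(ValueError):
            predict_decode(scaled_state, encode_cscn(seq, 1), 0)
        with pytest.raises(ValueError):
            predict_decode(scaled_state, encode_cscn(seq, 2), 2)


def _tiny_samples(rng, cfg, n, zero=False):
    samples = []
    for _ in range(n):
        seqs = tuple("".join(rng.choice(list("ACGT"), cfg.window_bp)) for _ in range(2))
        target = np.zeros(cfg.pole_length) if zero else rng.poisson(20, cfg.pole_length).astype(float)
        samples.append(TrainSample(seqs, (1, 1), target))
    return samples


class TestTraining:
    def test_zero_targets_converge_to_zero(self, rng):
        cfg = tiny_cfg()
        state = build_predictor(cfg, seed=1)
        samples = _tiny_samples(rng, cfg, 6, zero=True)
        train_total(state, samples, TrainHyper(max_epochs=3, seed=1))
        pred = predict_pole(state, encode_cscn(samples[0].seqs[0], 1))
        assert float(np.mean(pred**2)) < 1.0
        assert state.history[-1]["train_mse"] < state.history[0]["train_mse"] + 1e-9

    def test_training_loss_nonincreasing_within_tolerance(self, rng):
        # a learnable (near-convex) fixture: per-distance constant targets
        cfg = tiny_cfg()
        state = build_predictor(cfg, seed=2)
        decay = 50.0 / np.arange(1, cfg.pole_length + 1)
        samples = []
        for _ in range(8):
            seqs = tuple("".join(rng.choice(list("ACGT"), cfg.window_bp)) for _ in range(2))
            samples.append(TrainSample(seqs, (1, 1), decay + rng.normal(0, 0.5, cfg.pole_length)))
        train_total(state, samples, TrainHyper(max_epochs=4, seed=2))
        losses = [h["train_mse"] for h in state.history]
        for prev, cur in zip(losses, losses[1:]):
            assert cur <= prev * 1.05  # allow small transient increases

    def test_more_than_two_contigs_rejected(self, rng):
        with pytest.raises(ValueError):
            TrainSample(("A" * 10, "C" * 10, "G" * 10), (1, 1, 1), np.zeros(3))

    def test_best_validation_state_kept(self, rng):
        cfg = tiny_cfg()
        state = build_predictor(cfg, seed=3)
        samples = _tiny_samples(rng, cfg, 6)
        val = _tiny_samples(rng, cfg, 2)
        train_total(state, samples, TrainHyper(max_epochs=3, seed=3), val_samples=val)
        assert len(state.history) == 3
        assert all(np.isfinite(h["val_mse"]) for h in state.history)


class TestContigPrediction:
    def test_band_is_symmetric_and_limited(self, rng):
        cfg = tiny_cfg()
        state = build_predictor(cfg, seed=4)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        cm = predict_contig_matrix(state, seq, strand_average=False)
        m = cm.matrix
        n = m.shape[0]
        band = cfg.window_bins - 1
        assert np.array_equal(np.isnan(m), np.isnan(m.T))
        filled = ~np.isnan(m)
        assert np.allclose(m[filled], m.T[filled])
        iu = np.triu_indices(n)
        for i, j in zip(*iu):
            if j - i > band:
                assert np.isnan(m[i, j])

    def test_contig_shorter_than_window_rejected(self, rng):
        cfg = tiny_cfg()
        state = build_predictor(cfg, seed=4)
        with pytest.raises(ValueError):
            predict_contig_matrix(state, "ACGT" * 100)


class TestTransfer:
    def test_shared_weights_copied_bit_identical(self):
        small = build_predictor(tiny_cfg(), seed=5)
        cfg_large = PredictorConfig(
            conv_units=(6, 8), conv_kernels=(5, 3), pool_widths=(4, 2),
            dilated_units=5, dilation_rates=(1, 2, 1),
            window_bp=8_000, resolution=500,
        )
        large = transfer_weights(small, cfg_large)
        from neohic.predictor import _shared_params
        for a, b in zip(_shared_params(small.net, small.cfg), _shared_params(large.net, cfg_large)):
            assert np.array_equal(a.value, b.value)
        assert large.cfg.pole_length == 15

    def test_incompatible_stacks_rejected(self):
        small = build_predictor(tiny_cfg(), seed=5)
        other = PredictorConfig(
            conv_units=(4, 8), conv_kernels=(5, 3), pool_widths=(4, 2),
            dilated_units=5, dilation_rates=(1, 2, 1),
            window_bp=8_000, resolution=500,
        )
        with pytest.raises(ValueError):
            transfer_weights(small, other)

    def test_two_megabase_target_length(self):
        assert PredictorConfig.two_megabase().pole_length == 49


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        cfg = tiny_cfg()
        state = build_predictor(cfg, seed=6)
        state.target_scale = 3.5
        x = encode_cscn("".join(rng.choice(list("ACGT"), cfg.window_bp)), 1)
        before = predict_pole(state, x)
        p = tmp_path / "model.npz"
        save_checkpoint(state, p)
        back = load_checkpoint(p)
        assert np.allclose(predict_pole(back, x), before)
        assert back.cfg == cfg
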