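"""Context aggregation network: architecture, gradients, training contracts."""

import numpy as np
import pytest

import qpiphase as q
from qpiphase.can import CAN, CANConfig, TrainConfig
from qpiphase.datasets import DatasetRecord, ParameterSet


def _toy_records(n, channels=1, size=32, seed=0):
    """Smooth synthetic input/label pairs for optimization tests."""
    rng = np.random.default_rng(seed)
    recs = []
    yy, xx = np.mgrid[0:size, 0:size] / size
    for i in range(n):
        a, b, c = rng.uniform(-1, 1, 3)
        label = np.sin(4 * a * xx + 3 * b * yy) + c
        inputs = np.stack([label + 0.05 * rng.normal(size=label.shape)
                           for _ in range(channels)])
        p = ParameterSet("spr", 40.0, 1.0, 633.0, gold_scale=1.0)
        recs.append(DatasetRecord(inputs.astype(np.float32), label, p, "CAN1", ()))
    return recs


class _Split:
    def __init__(self, train, validation=()):
        self.train = list(train)
        self.validation = list(validation)
        self.fraction = 1.0


class TestArchitecture:
    def test_parameter_count_closed_form(self):
        # independent arithmetic over the layer table for N=1, M=64:
        # first conv + 8 dilated convs + 9 adaptive norms + final 1x1 conv
        M = 64
        conv1 = 3 * 3 * 1 * M + M
        convs = 8 * (3 * 3 * M * M + M)
        adanorm = 9 * (2 * M + 2)       # gamma, beta per channel + 2 mix scalars
        final = M * 1 + 1
        model = q.build_can(CANConfig(input_channels=1, features=64))
        assert model.n_params == conv1 + convs + adanorm + final

    def test_receptive_field_covers_input_at_dilation_128(self):
        cfg = CANConfig(input_channels=1, features=8, input_size=256)
        partial = 1 + 2 * sum(cfg.dilations[:8])
        assert partial == 511
        assert partial >= cfg.input_size
        assert cfg.receptive_field == 1 + 2 * sum(cfg.dilations)

    def test_dilation_schedule(self):
        cfg = CANConfig()
        assert cfg.dilations == (1, 2, 4, 8, 16, 32, 64, 128, 1)
        assert cfg.lrelu_scales == (0.2,) * 8 + (0.01,)

    @pytest.mark.parametrize("size", [32, 64])
    def test_forward_shape_and_finiteness(self, size):
        model = q.build_can(CANConfig(input_channels=2, features=4), seed=1)
        out = model.forward(np.zeros((2, size, size), dtype=np.float32))
        assert out.shape == (size, size)
        assert np.all(np.isfinite(out))

    def test_input_validation(self):
        model = q.build_can(CANConfig(input_channels=1, features=4))
        with pytest.raises(ValueError):
            model.forward(np.zeros((3, 16, 16)))
        with pytest.raises(ValueError):
            CANConfig(input_channels=0, features=4)

    def test_adaptive_norm_identity_when_mix_weight_zero(self):
        model = q.build_can(CANConfig(input_channels=1, features=4), seed=2)
        x = np.random.default_rng(3).normal(size=(1, 16, 16)).astype(np.float32)
        base = model.forward(x)
        # m{l} = 0 at init: the normalized branch (gamma, beta) must be inert
        for l in range(9):
            model.params[f"g{l}"] = model.params[f"g{l}"] * 7.0
            model.params[f"c{l}"] = model.params[f"c{l}"] + 3.0
        assert np.array_equal(model.forward(x), base)


class TestConvolutionOracle:
    @pytest.mark.parametrize("dilation", [1, 2, 4])
    def test_first_level_matches_scipy_dilated_correlation(self, dilation):
        """The im2col convolution equals scipy correlate2d with a
        zero-inflated (dilated) kernel."""
        from scipy.signal import correlate2d
        cfg = CANConfig(input_channels=2, features=3, input_size=12,
                        dilations=(dilation,), lrelu_scales=(1.0,))
        model = q.build_can(cfg, seed=8)
        model.params["a0"] = np.float32(1.0)
        model.params["m0"] = np.float32(0.0)
        rng = np.random.default_rng(9)
        x = rng.normal(size=(2, 12, 12)).astype(np.float32)
        # lrelu with slope 1 is the identity and m=0 disables the norm
        # branch, but the instance-norm path still mixes via a0*y only
        got = model.forward(x)
        W, b = model.params["W0"], model.params["b0"]
        expect = np.zeros((3, 12, 12))
        for m in range(3):
            acc = np.full((12, 12), float(b[m]))
            for c in range(2):
                k = np.zeros((2 * dilation + 1,) * 2)
                k[::dilation, ::dilation] = W[m, c]
                acc += correlate2d(x[c], k, mode="same")
            expect[m] = acc
        pred = model.params["Wf"] @ expect.reshape(3, -1) + model.params["bf"][:, None]
        assert np.abs(got - pred.reshape(12, 12)).max() < 1e-4


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = CANConfig(input_channels=2, features=3, input_size=8,
                        dilations=(1, 2, 1), lrelu_scales=(0.2, 0.2, 0.01))
        model = q.build_can(cfg, seed=4)
        # move the norm-mix weights off zero so every parameter participates
        for l in range(3):
            model.params[f"m{l}"] = np.float32(0.5)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 8, 8)).astype(np.float32)
        y = rng.normal(size=(8, 8)).astype(np.float32)
        _, grads = model.loss_and_grads(x, y)
        eps = 1e-2
        for key in ["W0", "b1", "a1", "m2", "g0", "c2", "Wf", "bf"]:
            p = model.params[key]
            flat_idx = 0  # probe the first element of each parameter array
            def poke(v):
                arr = np.array(p, dtype=np.float64).copy()
                arr.flat[flat_idx] += v
                model.params[key] = arr.astype(np.float32) if np.ndim(p) else np.float32(arr)
                loss, _ = model.loss_and_grads(x, y)
                return loss
            num = (poke(eps) - poke(-eps)) / (2 * eps)
            model.params[key] = p
            ana = np.asarray(grads[key]).flat[0]
            assert num == pytest.approx(ana, rel=0.05, abs=2e-4), key

    def test_loss_head_equals_mean_squared_residual(self):
        model = q.build_can(CANConfig(input_channels=1, features=4), seed=6)
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 16, 16)).astype(np.float32)
        y = rng.normal(size=(16, 16)).astype(np.float32)
        loss, _ = model.loss_and_grads(x, y)
        pred = model.forward(x)
        assert loss == pytest.approx(float(np.mean((pred - y) ** 2)), rel=1e-6)


class TestTraining:
    def test_seed_determinism(self):
        recs = _toy_records(4, size=16)
        losses = []
        for _ in range(2):
            model = q.build_can(CANConfig(input_channels=1, features=4,
                                          input_size=16), seed=11)
            q.train(model, _Split(recs), TrainConfig(1e-3, 1, 1, seed=12))
            losses.append(model.history["train_loss"][0])
        assert losses[0] == losses[1]

    def test_overfits_tiny_dataset(self):
        recs = _toy_records(2, size=32, seed=1)
        model = q.build_can(CANConfig(input_channels=1, features=4,
                                      input_size=32), seed=13)
        q.train(model, _Split(recs), TrainConfig(1e-3, 1, 150, seed=14))
        h = model.history["train_loss"]
        assert h[-1] < 0.1 * h[0]
        # smoothed trend is downward
        sm = np.convolve(h, np.ones(10) / 10, mode="valid")
        assert sm[-1] < sm[0]
        pred = q.predict(model, recs[0].inputs)
        assert np.median(np.abs(pred - recs[0].label)) < 0.2

    def test_channel_mismatch_and_empty_dataset(self):
        model = q.build_can(CANConfig(input_channels=2, features=4))
        with pytest.raises(ValueError):
            q.train(model, _Split(_toy_records(2, channels=1, size=16)),
                    TrainConfig(1e-3, 1, 1))
        with pytest.raises(ValueError):
            q.train(model, _Split([]), TrainConfig(1e-3, 1, 1))

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(minibatch=4)


class TestPredictAndAblation:
    def test_batch_order_preserved(self):
        model = q.build_can(CANConfig(input_channels=1, features=4), seed=15)
        rng = np.random.default_rng(16)
        batch = rng.normal(size=(3, 1, 16, 16)).astype(np.float32)
        out = q.predict(model, batch)
        assert out.shape == (3, 16, 16)
        for i in range(3):
            assert np.array_equal(out[i], model.forward(batch[i]))

    def test_prediction_deterministic(self):
        model = q.build_can(CANConfig(input_channels=1, features=4), seed=17)
        x = np.ones((1, 16, 16), dtype=np.float32)
        assert np.array_equal(q.predict(model, x), q.predict(model, x))

    def test_ablate_channel(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(2, 8, 8))
        once = q.ablate_channel(x, 0)
        assert np.all(once[0] == 0) and np.array_equal(once[1], x[1])
        assert np.array_equal(q.ablate_channel(once, 0), once)  # idempotent
        both = q.ablate_channel(once, 1)
        assert np.all(both == 0)
        with pytest.raises(IndexError):
            q.ablate_channel(x, 2)

    def test_checkpoint_round_trip(self, tmp_path):
        model = q.build_can(CANConfig(input_channels=1, features=4), seed=19)
        x = np.random.default_rng(20).normal(size=(1, 16, 16)).astype(np.float32)
        model.save(tmp_path / "model")
        loaded = CAN.load(tmp_path / "model")
        assert np.array_equal(loaded.forward(x), model.forward(x))
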