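"""Torsion Transformer: grid, forward contracts, losses, training rules."""

import numpy as np
import pytest

from torsionlab import nn
from torsionlab.errors import ConfigurationError
from torsionlab.preprocess import RotationSample, rotate_box
from torsionlab.torsion_model import (AngleGrid, TorsionNetConfig,
                                      TorsionTransformer, angle_grid,
                                      decoder_loss, estimate_series,
                                      finder_loss, load_checkpoint,
                                      retained_for_eval, save_checkpoint,
                                      softmax_expectation, total_loss,
                                      train_torsion_transformer)

from helpers import mse_pixel_loop


@pytest.fixture(scope="module")
def tiny_cfg():
    return TorsionNetConfig.small(max_epochs=2, batch_size=8, seed=1)


@pytest.fixture(scope="module")
def tiny_model(tiny_cfg):
    return TorsionTransformer(tiny_cfg)


def _toy_samples(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        stack = rng.random((3, 64, 64)).astype(np.float32)
        theta = float(rng.uniform(-15, 15))
        rot = np.stack([rotate_box(f, theta) for f in stack])
        out.append(RotationSample(original=stack, theta_gt=theta,
                                  rotated=rot))
    return out


class TestAngleGrid:
    @pytest.mark.parametrize("lo,hi,step,expect", [
        (-15, 15, 1, 31),
        (0, 0, 1, 1),
        (-2, 2, 1, 5),
    ])
    def test_grid_length(self, lo, hi, step, expect):
        g = angle_grid(lo, hi, step)
        assert len(g) == expect
        assert np.allclose(np.diff(g.angles), step) or expect == 1

    def test_default_grid_is_symmetric_31(self):
        g = AngleGrid()
        assert len(g) == 31
        assert np.allclose(g.angles, np.arange(-15, 16))
        assert np.allclose(g.angles + g.angles[::-1], 0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            angle_grid(-15, 15, 0)
        with pytest.raises(ConfigurationError):
            angle_grid(-15, 14, 4)    # span not divisible by the step

    def test_nearest_index(self):
        g = AngleGrid()
        assert g.nearest_index(0.4) == 15
        assert g.nearest_index(-15.0) == 0
        assert g.nearest_index(20.0) == 30


class TestForwardContracts:
    def test_skip_block_output_shape(self, tiny_model):
        frame = nn.Tensor(np.random.default_rng(0)
                          .random((2, 64, 64, 1), dtype=np.float32))
        out = tiny_model.skip_block_forward(frame, 0)
        assert out.shape == (2, 64, 64, 31)

    def test_zero_frame_zero_biases_gives_zero_features(self, tiny_cfg):
        m = TorsionTransformer(tiny_cfg)
        frame = nn.Tensor(np.zeros((1, 64, 64, 1), dtype=np.float32))
        out = m.skip_block_forward(frame, 0)
        assert np.allclose(out.data, 0.0)

    def test_decoder_output_shape_and_determinism(self, tiny_model):
        rng = np.random.default_rng(3)
        stack = nn.Tensor(rng.random((2, 3, 64, 64), dtype=np.float32))
        retained = np.array([[0, 15, 30], [3, 4, 5]])
        a = tiny_model.decoder_forward(stack, retained)
        b = tiny_model.decoder_forward(stack, retained)
        assert a.shape == (2, 3, 64, 64)
        assert np.array_equal(a.data, b.data)

    def test_decoder_rejects_duplicate_retained(self, tiny_model):
        stack = nn.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
        with pytest.raises(ConfigurationError):
            tiny_model.decoder_forward(stack, np.array([[4, 4, 9]]))

    def test_finder_prediction_always_within_grid(self, tiny_model):
        rng = np.random.default_rng(4)
        stacks = nn.Tensor(rng.random((8, 3, 64, 64), dtype=np.float32) * 5)
        _, theta = tiny_model.finder_forward(stacks)
        assert np.all(theta.data >= -15) and np.all(theta.data <= 15)

    def test_retained_for_eval_neighbours(self):
        g = AngleGrid()
        sel = retained_for_eval(g, np.array([0.2, -15.0, 14.8]))
        assert sel.tolist() == [[14, 15, 16], [0, 1, 2], [28, 29, 30]]


class TestSoftmaxExpectation:
    def test_uniform_logits_give_zero(self):
        g = AngleGrid()
        assert softmax_expectation(np.zeros(31), g.angles) == pytest.approx(0)

    def test_one_hot_limit_hits_anchor_angle(self):
        g = AngleGrid()
        logits = np.zeros(31)
        logits[g.nearest_index(7)] = 1e4
        assert softmax_expectation(logits, g.angles) == pytest.approx(7.0)

    def test_symmetric_mass_cancels(self):
        g = AngleGrid()
        logits = np.zeros(31)
        logits[g.nearest_index(10)] = 50.0
        logits[g.nearest_index(-10)] = 50.0
        assert softmax_expectation(logits, g.angles) == pytest.approx(0.0)


class TestLosses:
    def test_decoder_loss_closed_forms(self):
        a = np.zeros((3, 64, 64))
        assert decoder_loss(a, a) == 0.0
        assert decoder_loss(a + 2.5, a) == pytest.approx(2.5 ** 2)

    def test_decoder_loss_matches_pixel_loop(self):
        rng = np.random.default_rng(5)
        a = rng.random((3, 8, 8))
        b = rng.random((3, 8, 8))
        assert decoder_loss(a, b) == pytest.approx(mse_pixel_loop(a, b),
                                                   rel=1e-9)

    @pytest.mark.parametrize("e,expect", [
        (0.0, 0.0),
        (0.5, 0.125),
        (3.0, 2.5),
        (-3.0, 2.5),
    ])
    def test_huber_closed_forms(self, e, expect):
        assert finder_loss(0.0, e, delta=1.0) == pytest.approx(expect)

    def test_huber_continuous_and_smooth_at_delta(self):
        d = 1.0
        eps = 1e-7
        below = finder_loss(0.0, d - eps, d)
        above = finder_loss(0.0, d + eps, d)
        assert abs(above - below) < 1e-6          # continuity
        slope_below = (finder_loss(0.0, d, d)
                       - finder_loss(0.0, d - eps, d)) / eps
        slope_above = (finder_loss(0.0, d + eps, d)
                       - finder_loss(0.0, d, d)) / eps
        assert slope_below == pytest.approx(d, abs=1e-3)
        assert slope_above == pytest.approx(d, abs=1e-3)

    def test_total_loss_is_plain_sum(self):
        assert total_loss(0.0, 0.0) == 0.0
        assert total_loss(1.5, 0.25) == 1.75

    def test_shared_anchor_gradient_is_sum_of_per_loss_gradients(self):
        """d(total)/d(anchors) must equal the sum of the decoder-only and
        finder-only gradients (additivity of the joint objective)."""
        cfg = TorsionNetConfig.small(seed=2)
        model = TorsionTransformer(cfg)
        rng = np.random.default_rng(6)
        stack = nn.Tensor(rng.random((2, 3, 64, 64), dtype=np.float32))
        rot = rng.random((2, 3, 64, 64), dtype=np.float32)
        retained = np.array([[1, 2, 3], [10, 20, 30]])
        th = np.array([2.0, -4.0])

        def grads(with_dec, with_fin):
            model.anchors.grad = None
            parts = []
            if with_dec:
                recon = model.decoder_forward(stack, retained)
                d = recon - nn.Tensor(rot)
                parts.append((d * d).mean())
            if with_fin:
                _, theta = model.finder_forward(stack)
                parts.append(nn.huber(theta, th, 1.0))
            loss = parts[0] if len(parts) == 1 else parts[0] + parts[1]
            loss.backward()
            return model.anchors.grad.copy()

        g_both = grads(True, True)
        g_dec = grads(True, False)
        g_fin = grads(False, True)
        assert np.allclose(g_both, g_dec + g_fin, rtol=1e-4, atol=1e-7)


class TestTraining:
    def test_zero_learning_rate_changes_nothing(self):
        samples = _toy_samples(16, seed=1)
        cfg = TorsionNetConfig.small(max_epochs=3, batch_size=8,
                                     learning_rate=0.0, seed=3)
        ref = TorsionTransformer(cfg)
        model, hist = train_torsion_transformer(samples, cfg)
        for a, b in zip(model.parameters(), ref.parameters()):
            assert np.array_equal(a.data, b.data)
        assert hist.finder_loss[0] == pytest.approx(hist.finder_loss[-1],
                                                    rel=1e-5)

    def test_same_seed_identical_history(self):
        samples = _toy_samples(16, seed=2)
        cfg = TorsionNetConfig.small(max_epochs=2, batch_size=8, seed=4)
        _, h1 = train_torsion_transformer(samples, cfg, samples[:4])
        _, h2 = train_torsion_transformer(samples, cfg, samples[:4])
        assert h1.total_loss == h2.total_loss
        assert h1.val_mae_deg == h2.val_mae_deg

    def test_history_total_is_sum_of_parts(self):
        samples = _toy_samples(12, seed=3)
        cfg = TorsionNetConfig.small(max_epochs=2, batch_size=4, seed=5)
        _, hist = train_torsion_transformer(samples, cfg)
        for d, f, t in zip(hist.decoder_loss, hist.finder_loss,
                           hist.total_loss):
            assert t == pytest.approx(d + f, rel=1e-9)


class TestEstimateSeries:
    def test_one_value_per_three_frames(self, tiny_model):
        rng = np.random.default_rng(7)
        frames = rng.random((30, 64, 64), dtype=np.float32)
        ts = estimate_series(frames, tiny_model)
        assert len(ts.angles_deg) == 10
        assert np.allclose(np.diff(ts.times_s), 0.1)

    @pytest.mark.parametrize("n", [31, 32])
    def test_remainder_frames_dropped(self, tiny_model, n):
        rng = np.random.default_rng(8)
        frames = rng.random((n, 64, 64), dtype=np.float32)
        assert len(estimate_series(frames, tiny_model).angles_deg) == 10

    def test_identical_triples_identical_angles(self, tiny_model):
        rng = np.random.default_rng(9)
        triple = rng.random((3, 64, 64), dtype=np.float32)
        frames = np.concatenate([triple, triple, triple])
        ts = estimate_series(frames, tiny_model)
        # equal up to BLAS batch-position blocking (~1e-6 deg)
        assert np.allclose(ts.angles_deg, ts.angles_deg[0], atol=1e-3)


def test_checkpoint_round_trip(tmp_path, tiny_model):
    path = tmp_path / "ckpt.npz"
    save_checkpoint(tiny_model, path)
    loaded = load_checkpoint(path)
    rng = np.random.default_rng(10)
    stacks = rng.random((4, 3, 64, 64), dtype=np.float32)
    assert np.allclose(tiny_model.predict_angles(stacks),
                       loaded.predict_angles(stacks))
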