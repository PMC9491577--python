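"""The sinc filter bank, attention gate, and full classifier stack."""

import numpy as np
import pytest

from sincdecode import nn
from sincdecode.autodiff import Tensor
from sincdecode.model import (ModelConfig, SEAttention, SincEEGNet,
                              SincFilterBank, extract_attention,
                              load_checkpoint, predict_proba,
                              save_checkpoint, summary)

rng = np.random.default_rng(0)


class TestSincFilterBank:
    def test_floors_force_minimum_passband(self):
        bank = SincFilterBank(n_filters=1, rate_hz=250.0)
        bank.raw_low.data[:] = 0.0
        bank.raw_band.data[:] = 0.0
        f1, f2 = bank.cutoffs()
        assert f1[0] == pytest.approx(1.0)
        assert f2[0] == pytest.approx(5.0)

    def test_negative_raw_low_maps_through_absolute_value(self):
        bank = SincFilterBank(n_filters=1)
        bank.raw_low.data[:] = -3.0
        f1, _ = bank.cutoffs()
        assert f1[0] == pytest.approx(4.0)

    @pytest.mark.parametrize("f1,band,lo,hi", [
        (8.0, 4.0, 8.0, 12.0),
        (20.0, 10.0, 20.0, 30.0),
        (2.0, 4.0, 1.0, 7.0),  # peak of a low band sits inside [f1, f2]
    ])
    def test_kernel_spectrum_peaks_inside_passband(self, f1, band, lo, hi):
        bank = SincFilterBank(n_filters=1, kernel_len=65, rate_hz=250.0)
        bank.raw_low.data[:] = f1 - bank.freq_min
        bank.raw_band.data[:] = band - bank.band_min
        k = bank.kernels().data[0]
        freqs = np.fft.rfftfreq(1024, d=1 / 250.0)
        mag = np.abs(np.fft.rfft(k, 1024))
        peak = freqs[mag.argmax()]
        assert lo <= peak <= hi

    def test_kernels_are_unit_energy(self):
        bank = SincFilterBank(n_filters=4)
        e = (bank.kernels().data ** 2).sum(axis=1)
        np.testing.assert_allclose(e, 1.0, atol=1e-12)

    def test_cutoff_parameters_receive_gradient(self):
        bank = SincFilterBank(n_filters=2)
        loss = (bank.kernels() * rng.normal(size=(2, 65))).sum()
        loss.backward()
        assert np.abs(bank.raw_low.grad).max() > 0
        assert np.abs(bank.raw_band.grad).max() > 0

    def test_even_kernel_length_rejected(self):
        with pytest.raises(ValueError):
            SincFilterBank(kernel_len=64)


class TestSEAttention:
    def test_zero_weights_give_half_gate_and_1p5x_output(self):
        att = SEAttention(4, reduction=2, rng=np.random.default_rng(0))
        for p in att.parameters():
            p.data[:] = 0.0
        x = Tensor(rng.normal(size=(3, 4, 10)))
        out, a = att(x)
        np.testing.assert_allclose(a.data, 0.5)
        np.testing.assert_allclose(out.data, 1.5 * x.data)

    def test_gate_values_strictly_inside_unit_interval(self):
        att = SEAttention(8, reduction=4, rng=np.random.default_rng(1))
        _, a = att(Tensor(rng.normal(size=(5, 8, 20))))
        assert np.all(a.data > 0.0) and np.all(a.data < 1.0)

    def test_two_map_toy_matches_hand_computation(self):
        att = SEAttention(2, reduction=1, rng=np.random.default_rng(2))
        # shared MLP: identity-ish weights set by hand
        att.fc1.weight.data = np.array([[1.0, 0.0], [0.0, 1.0]])
        att.fc1.bias.data = np.zeros(2)
        att.fc2.weight.data = np.array([[0.5, 0.0], [0.0, -0.5]])
        att.fc2.bias.data = np.array([0.1, 0.2])
        x = np.array([[[1.0, 3.0, 2.0, 2.0], [-1.0, 0.0, -2.0, -1.0]]])
        out, a = att(Tensor(x))
        # avg pool: (2, -1); max pool: (3, 0); relu then shared MLP
        h_avg = np.maximum([2.0, -1.0], 0)
        h_max = np.maximum([3.0, 0.0], 0)
        z = (h_avg @ att.fc2.weight.data + att.fc2.bias.data
             + h_max @ att.fc2.weight.data + att.fc2.bias.data)
        expected_a = 1 / (1 + np.exp(-z))
        np.testing.assert_allclose(a.data[0], expected_a, atol=1e-12)
        np.testing.assert_allclose(
            out.data[0], x[0] * (1 + expected_a[:, None]), atol=1e-12)

    def test_reduction_must_divide_map_count(self):
        with pytest.raises(ValueError):
            SEAttention(6, reduction=4, rng=np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_model():
    cfg = ModelConfig(n_channels=6, n_samples=125, n_classes=5,
                      n_filters=4, se_reduction=2, dense1=16, dense2=32,
                      dropout=0.25, seed=1)
    return SincEEGNet(cfg)


class TestForward:
    def test_output_shapes_and_simplex(self, small_model):
        x = rng.normal(size=(8, 6, 125))
        out = small_model(x)
        assert out.logits.shape == (8, 5)
        assert out.features.shape == (8, 32)
        assert out.attention.shape == (8, 8)
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(out.probs >= 0)

    def test_flatten_width_is_320_at_full_scale(self):
        assert ModelConfig().flat_width == 32 * 10

    def test_shape_mismatch_reports_expectation(self, small_model):
        with pytest.raises(ValueError, match="expected input"):
            small_model(rng.normal(size=(2, 6, 100)))

    def test_depthwise_spatial_equals_bruteforce_projection(self):
        """The depthwise layer projects each band's 128-channel pattern
        through its own spatial kernels — checked against an explicit loop
        on a 3-channel, 5-sample toy."""
        x = rng.normal(size=(2, 2, 3, 5))   # batch, bands, channels, time
        w = rng.normal(size=(2, 2, 3))      # bands, multiplier, channels
        out = nn.spatial_collapse(Tensor(x), Tensor(w)).data
        expected = np.zeros((2, 4, 5))
        for b in range(2):
            for f in range(2):
                for m in range(2):
                    for t in range(5):
                        expected[b, f * 2 + m, t] = w[f, m] @ x[b, f, :, t]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_training_step_moves_sinc_cutoffs(self, small_model):
        """Gradient flows through the kernel construction to the cutoff
        parameters: one optimization step changes the effective bands."""
        model = SincEEGNet(small_model.config)
        model.train()
        x = rng.normal(size=(12, 6, 125))
        y = rng.integers(0, 5, size=12)
        before = np.concatenate(model.sinc.cutoffs())
        opt = nn.Adam(model.parameters(), lr=1e-2)
        out = model(x)
        loss = nn.cross_entropy(out.logits, y)
        loss.backward()
        assert np.abs(model.sinc.raw_low.grad).max() > 0
        opt.step()
        after = np.concatenate(model.sinc.cutoffs())
        assert not np.allclose(before, after)


class TestEvaluationMode:
    def test_attention_extraction_is_deterministic(self, small_model):
        x = rng.normal(size=(4, 6, 125))
        a1 = extract_attention(small_model, x)
        a2 = extract_attention(small_model, x)
        np.testing.assert_array_equal(a1, a2)
        assert a1.shape == (4, 8)

    def test_mean_attention_matches_external_average(self, small_model):
        x = rng.normal(size=(6, 6, 125))
        attn = extract_attention(small_model, x, batch_size=2)
        from sincdecode.interpretation import average_attention
        np.testing.assert_allclose(average_attention(attn),
                                   attn.mean(axis=0), atol=1e-15)

    def test_checkpoint_roundtrip_preserves_predictions(self, small_model,
                                                        tmp_path):
        x = rng.normal(size=(3, 6, 125))
        p1 = predict_proba(small_model, x)
        save_checkpoint(small_model, tmp_path / "m.npz")
        restored = load_checkpoint(tmp_path / "m.npz")
        p2 = predict_proba(restored, x)
        np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_summary_reports_full_stack_dimensions():
    text = summary(ModelConfig())
    assert "320" in text          # flatten width
    assert "2048" in text         # feature layer
    assert "kernel=65" in text
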