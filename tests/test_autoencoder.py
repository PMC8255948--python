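import numpy as np
import pytest

import petdect.nn as nn
from petdect import ConvAutoencoder, build_model, extract_cnn_features
from petdect.nn import REDCNN, UNet


@pytest.fixture(scope="module")
def ct32(grid64=None):
    rng = np.random.default_rng(0)
    base = np.zeros((32, 32))
    base[8:24, 8:24] = 1.0
    base[12:20, 12:20] = 0.5
    return base + 0.05 * rng.random((32, 32))


class TestArchitectureBudgets:
    def test_redcnn_parameter_count(self):
        assert REDCNN(width=60).n_params == pytest.approx(7e5, rel=0.1)

    def test_unet_parameter_count(self):
        model = UNet(image_shape=(180, 180))
        assert model.n_params == pytest.approx(3.4e5, rel=0.1)

    def test_unet_penultimate_has_12_channels(self):
        model = UNet(image_shape=(32, 32), channels=(4, 6, 8, 10))
        acts = model.forward(np.zeros((1, 32, 32), dtype=np.float32))
        assert acts["p"].shape == (12, 32, 32)

    def test_forward_pass_of_zeros_is_finite(self):
        for model in (REDCNN(width=4), UNet(image_shape=(16, 16),
                                            channels=(3, 4, 5))):
            out = model.forward(np.zeros((1, 16, 16), dtype=np.float32))["out"]
            assert out.shape == (1, 16, 16)
            assert np.all(np.isfinite(out))

    def test_odd_image_sizes_supported(self):
        model = UNet(image_shape=(21, 17), channels=(3, 4, 5))
        out = model.forward(np.zeros((1, 21, 17), dtype=np.float32))["out"]
        assert out.shape == (1, 21, 17)


class TestGradients:
    @pytest.mark.parametrize("factory", [
        lambda: REDCNN(width=3, seed=0),
        lambda: UNet(image_shape=(8, 8), channels=(3, 4, 5),
                     penultimate_channels=3, seed=0),
    ])
    def test_backward_matches_numerical_gradient(self, factory, monkeypatch):
        monkeypatch.setattr(nn, "DTYPE", np.float64)
        model = factory()
        rng = np.random.default_rng(1)
        x = rng.random((1, 8, 8))

        def loss():
            return float(np.sum((model.forward(x)["out"] - x) ** 2))

        acts = model.forward(x)
        model.backward(2.0 * (acts["out"] - x), acts)
        rs = np.random.default_rng(2)
        for p, g in zip(model.params(), model.grads()):
            idx = tuple(rs.integers(0, s) for s in p.shape)
            eps, orig = 1e-6, p[idx].copy()
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-5 * max(abs(num), 1e-3)


class TestTraining:
    def test_loss_decreases(self, ct32):
        ae = ConvAutoencoder(architecture="unet", epochs=60,
                             unet_channels=(8, 12, 16), seed=0).fit(ct32)
        losses = ae.loss_trace_.losses
        assert len(losses) == 60
        assert losses[-1] < losses[0]

    def test_seeded_rerun_bit_identical(self, ct32):
        kw = dict(architecture="unet", epochs=25, unet_channels=(6, 8, 10),
                  seed=3)
        a = ConvAutoencoder(**kw).fit(ct32)
        b = ConvAutoencoder(**kw).fit(ct32)
        assert a.loss_trace_.losses == b.loss_trace_.losses
        np.testing.assert_array_equal(a.transform(ct32).features,
                                      b.transform(ct32).features)

    def test_constant_image_is_learned_exactly(self):
        x = np.full((24, 24), 2.0)
        ae = ConvAutoencoder(architecture="redcnn", epochs=300, lr=3e-3,
                             redcnn_width=6, seed=0).fit(x)
        # residual architecture reproduces a constant almost perfectly
        assert np.sqrt(ae.loss_trace_.final_loss) <= 1e-4 * np.linalg.norm(
            np.ones(x.size))

    def test_divergence_raises_naming_learning_rate(self, ct32):
        with pytest.raises(FloatingPointError, match="lr"):
            ConvAutoencoder(architecture="unet", epochs=400, lr=1e3,
                            unet_channels=(6, 8, 10), seed=0).fit(ct32)


@pytest.fixture(scope="module")
def trained(ct32):
    return ConvAutoencoder(architecture="unet", epochs=30,
                           unet_channels=(6, 8, 10), seed=0).fit(ct32)


class TestFeatureExtraction:
    def test_one_row_per_pixel(self, trained, ct32):
        fmap = trained.transform(ct32)
        assert fmap.features.shape == (ct32.size, 12)
        assert np.all(np.isfinite(fmap.features))

    def test_extraction_is_deterministic(self, trained, ct32):
        f1 = trained.transform(ct32)
        f2 = trained.transform(ct32)
        np.testing.assert_array_equal(f1.features, f2.features)

    def test_invalid_layer_rejected(self, trained, ct32):
        with pytest.raises(ValueError, match="unknown feature layer"):
            extract_cnn_features(trained.model_, ct32, layer="nope")

    def test_downsampled_layer_rejected(self, trained, ct32):
        with pytest.raises(ValueError, match="spatial size"):
            extract_cnn_features(trained.model_, ct32, layer="e2")

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            build_model("vae", (32, 32))
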