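"""Keypoint CNN: normalization, reference convolution, architecture, training."""

import dataclasses

import numpy as np
import pytest

from nasoform import nn
from nasoform.errors import ConfigurationError, DataError, ParameterError
from nasoform.keypoint import (AugmentConfig, NetworkConfig, _flip_index,
                               augment_batch, build_keypoint_network,
                               conv_forward_reference, denormalize_image,
                               extractor_output_side, list_backbones,
                               normalize_image, predict_landmarks, relu,
                               resize_with_padding, train_keypoint_model)
from nasoform.landmarks import LandmarkSet

TINY = NetworkConfig(
    input_shape=(32, 32, 3), channels=(4, 6, 8, 8, 8),
    dense=(16, 8), batch_size=8, validation_split=0.25,
)


def _tiny_dataset(n, rng, size=32):
    """Blob-at-known-position images with matching ground truth."""
    from skimage.draw import disk

    codes = NetworkConfig(view="lateral").codes()
    data = []
    for i in range(n):
        img = np.full((size, size, 3), 180, dtype=np.uint8)
        pts = {}
        for j, c in enumerate(codes):
            x = 6 + ((i * 5 + j * 7) % (size - 12))
            y = 6 + ((i * 3 + j * 11) % (size - 12))
            rr, cc = disk((y, x), 1.5, shape=(size, size))
            img[rr, cc] = 30 + (j * 9) % 120
            pts[c] = (float(x), float(y))
        data.append((img, LandmarkSet(f"s{i}", "lateral", pts)))
    return data


class TestNormalizeImage:
    @pytest.mark.parametrize("pixel,sigma,expect", [
        (127.5, 1.0, 0.0),
        (255, 0.5, 1.0),
        (0, 1.0, -0.5),
    ])
    def test_known_values(self, pixel, sigma, expect):
        out = normalize_image(np.array([[pixel]]), sigma)
        assert out[0, 0] == pytest.approx(expect)

    def test_matches_scalar_formula(self, rng):
        img = rng.integers(0, 256, size=(4, 4))
        sigma = 0.37
        out = normalize_image(img, sigma)
        for a in range(4):
            for b in range(4):
                assert out[a, b] == pytest.approx((img[a, b] / 255 - 0.5) / sigma)

    def test_invertible(self, rng):
        img = rng.integers(0, 256, size=(5, 5, 3)).astype(float)
        back = denormalize_image(normalize_image(img, 0.21), 0.21)
        np.testing.assert_allclose(back, img, atol=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            normalize_image(np.zeros((2, 2)), 0.0)


class TestReferenceConvolution:
    def test_identity_filter(self, rng):
        x = rng.standard_normal((5, 5))
        out = conv_forward_reference(x, np.array([[1.0]]), 0.0, "identity")
        np.testing.assert_allclose(out, x)

    def test_zero_input_relu_bias(self):
        out = conv_forward_reference(np.zeros((6, 6)), np.ones((3, 3)), -2.0, "relu")
        np.testing.assert_allclose(out, 0.0)
        out = conv_forward_reference(np.zeros((6, 6)), np.ones((3, 3)), 2.0, "relu")
        np.testing.assert_allclose(out, 2.0)

    def test_output_size_is_valid_convolution(self, rng):
        out = conv_forward_reference(rng.standard_normal((5, 5)),
                                     rng.standard_normal((3, 3)))
        assert out.shape == (3, 3)

    def test_agrees_with_vectorised_layer(self, rng):
        for _ in range(20):
            x = rng.standard_normal((6, 6))
            layer = nn.Conv2D(1, 1, k=3, padding="valid", rng=rng, dtype=np.float64)
            ref = conv_forward_reference(x, layer.w[:, :, 0, 0], float(layer.b[0]))
            out = layer.forward(x[None, :, :, None])[0, :, :, 0]
            np.testing.assert_allclose(out, ref, atol=1e-12)


def test_relu_pointwise():
    assert relu(-2) == 0
    assert relu(3) == 3
    assert relu(0) == 0
    np.testing.assert_array_equal(relu(np.array([-1.0, 0.0, 2.5])), [0, 0, 2.5])


class TestArchitecture:
    def test_halving_arithmetic(self):
        assert extractor_output_side(224, (2, 2, 2, 2, 1)) == 14
        assert extractor_output_side(112, (2, 2, 2, 2, 1)) == 7
        for side in (64, 96, 160):
            assert extractor_output_side(side, (2, 2, 2, 2, 1)) == side // 16

    def test_tiny_summary_counts(self):
        model, summary = build_keypoint_network(TINY, seed=0)
        assert summary["conv_layers"] == 16
        assert summary["dense_layers"] == 3
        assert summary["pool_layers"] == 5
        assert summary["extractor_output_shape"] == (2, 2, 8)

    def test_reduced_extractor_runs(self, rng):
        model, _ = build_keypoint_network(TINY, seed=0)
        x = rng.standard_normal((1, 32, 32, 3)).astype(np.float32)
        assert model.extract_features(x).shape == (1, 2, 2, 8)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(TINY, dropout=1.0).validate()
        with pytest.raises(ConfigurationError):
            dataclasses.replace(TINY, validation_split=0.0).validate()
        with pytest.raises(ConfigurationError):
            dataclasses.replace(TINY, output_mode="heatmap").validate()

    def test_unavailable_backbone_adapter(self):
        cfg = dataclasses.replace(TINY, backbone="mobilenet")
        assert "mobilenet" in list_backbones()
        with pytest.raises(ConfigurationError, match="adapter"):
            build_keypoint_network(cfg)


class TestTraining:
    def test_loss_decreases_and_deterministic(self, rng):
        data = _tiny_dataset(24, rng)
        cfg = dataclasses.replace(TINY, epochs=5)
        model1, h1 = train_keypoint_model(data, cfg, seed=4)
        assert h1.val_loss[-1] < h1.val_loss[0]
        _, h2 = train_keypoint_model(data, cfg, seed=4)
        assert h1.train_loss[-1] == h2.train_loss[-1]

    def test_overfit_single_image(self, rng):
        # two copies of one image: the held-out half equals the trained half
        single = _tiny_dataset(1, rng)[0]
        data = [single, single]
        cfg = dataclasses.replace(TINY, epochs=300, validation_split=0.5,
                                  dropout=0.0, batch_size=1)
        model, hist = train_keypoint_model(data, cfg, seed=1)
        from nasoform.keypoint import _coords_matrix
        img, ls = data[0]
        pred = predict_landmarks(model, img)
        truth = _coords_matrix(ls, cfg.codes())
        got = _coords_matrix(pred, cfg.codes())
        assert np.abs(got - truth).mean() < 2.0

    def test_empty_dataset_raises(self):
        with pytest.raises(DataError):
            train_keypoint_model([], TINY, seed=0)


class TestPrediction:
    def test_predictions_within_bounds(self, rng):
        model, _ = build_keypoint_network(TINY, seed=0)
        model.sigma = 0.3
        img = rng.integers(0, 256, size=(32, 32, 3))
        ls = predict_landmarks(model, img)
        for x, y in ls.points.values():
            assert 0 <= x <= 31 and 0 <= y <= 31

    def test_resize_transform_round_trip(self, rng):
        img = rng.integers(0, 256, size=(60, 40, 3))
        out, scale, (pt, pl) = resize_with_padding(img, (32, 32))
        assert out.shape == (32, 32, 3)
        # a source point maps inside the padded frame and back exactly
        src = np.array([13.0, 27.0])
        mapped = src * scale + np.array([pl, pt])
        back = (mapped - np.array([pl, pt])) / scale
        np.testing.assert_allclose(back, src)

    def test_prediction_on_resized_input_lands_in_original_frame(self, rng):
        model, _ = build_keypoint_network(TINY, seed=0)
        model.sigma = 0.3
        img = rng.integers(0, 256, size=(64, 48, 3))
        ls = predict_landmarks(model, img)
        for x, y in ls.points.values():
            assert 0 <= x <= 47 and 0 <= y <= 63


class TestAugmentation:
    def test_flip_index_swaps_sides(self):
        codes = ("n", "al_R", "al_L", "prn")
        idx = _flip_index(codes)
        assert list(idx) == [0, 2, 1, 3]

    def test_hflip_moves_coordinates(self, rng):
        codes = ("n", "prn")
        imgs = rng.integers(0, 255, size=(1, 16, 16, 3)).astype(float)
        coords = np.array([[[2.0, 5.0], [10.0, 7.0]]])
        acfg = AugmentConfig(hflip_prob=1.0)
        out_i, out_c = augment_batch(imgs, coords, codes, acfg, rng)
        np.testing.assert_allclose(out_c[0, 0], [13.0, 5.0])
        np.testing.assert_allclose(out_i[0, :, 0], imgs[0, :, -1])
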