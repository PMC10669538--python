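import numpy as np
import pytest

import latentgrow as lg
from latentgrow import _nn
from latentgrow.autoencoder import (AutoencoderSpec, AutoencoderWeights,
                                    decode, encode)
from latentgrow.errors import ConfigurationError, InputError


def _np_conv_oracle(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                    relu: bool) -> np.ndarray:
    """Plain-loop convolution with reflection padding: independent of the
    packaged im2col forward path."""
    c_out, c_in, k, _ = W.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p)), mode="reflect")
    h, w = x.shape[1] - 2 * p, x.shape[2] - 2 * p
    out = np.zeros((c_out, h, w), dtype=np.float64)
    for co in range(c_out):
        acc = np.zeros((h, w))
        for ci in range(c_in):
            for i in range(k):
                for j in range(k):
                    acc += W[co, ci, i, j] * x[ci, i:i + h, j:j + w]
        out[co] = acc + b[co]
    if relu:
        out = np.maximum(out, 0.0)
    return out


def _np_pool_oracle(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    ho, wo = -(-h // 2), -(-w // 2)
    out = np.full((c, ho, wo), -np.inf)
    for i in range(h):
        for j in range(w):
            out[:, i // 2, j // 2] = np.maximum(out[:, i // 2, j // 2],
                                                x[:, i, j])
    return out


class TestEncode:
    def test_default_spec_latent_geometry(self):
        spec = AutoencoderSpec()
        assert spec.latent_channels == 256
        assert spec.n_pools == 2
        # a 512x512 image maps to a 256 x 128 x 128 latent grid
        names = [n for n, *_ in spec.encoder_layers()]
        assert names == ["enc_conv0", "enc_conv1_1", "enc_conv1_2",
                         "enc_pool1", "enc_conv2_1", "enc_conv2_2",
                         "enc_pool2", "enc_conv3_1"]

    def test_latent_shape_is_quarter_resolution(self, random_weights, rng):
        img = rng.uniform(size=(64, 64))
        latent = encode(img, random_weights)
        assert latent.values.shape == (32, 16, 16)
        assert latent.source_shape == (64, 64)

    def test_deterministic_bitwise(self, random_weights):
        img = np.zeros((32, 32))
        a = encode(img, random_weights).values
        b = encode(img, random_weights).values
        assert np.array_equal(a, b)

    def test_matches_layer_by_layer_oracle(self, random_weights, rng):
        img = rng.uniform(size=(16, 16))
        latent = encode(img, random_weights).values
        x = np.repeat(img[None].astype(np.float32), 3, axis=0) \
            .astype(np.float64)
        for layer in random_weights.encoder:
            if isinstance(layer, _nn.Conv2d):
                x = _np_conv_oracle(x, layer.W.astype(np.float64),
                                    layer.b.astype(np.float64), layer.relu)
            else:
                x = _np_pool_oracle(x)
        np.testing.assert_allclose(latent, x, rtol=1e-4, atol=1e-5)

    def test_out_of_range_image_rejected(self, random_weights):
        with pytest.raises(InputError):
            encode(np.full((32, 32), 1.5), random_weights)


class TestDecode:
    @pytest.mark.parametrize("shape", [(32, 32), (64, 48), (100, 36)])
    def test_round_trip_preserves_shape(self, random_weights, rng, shape):
        img = rng.uniform(size=shape)
        out = decode(encode(img, random_weights), random_weights)
        assert out.shape == shape

    def test_odd_sizes_round_trip(self, random_weights, rng):
        img = rng.uniform(size=(37, 53))   # ceil-mode pooling path
        out = decode(encode(img, random_weights), random_weights)
        assert out.shape == (37, 53)

    def test_output_clamped(self, random_weights, rng):
        out = decode(encode(rng.uniform(size=(32, 32)), random_weights),
                     random_weights)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_zero_latent_decodes_to_constant_image(self, random_weights):
        latent = lg.LatentFeature(values=np.zeros((32, 8, 8),
                                                  dtype=np.float32),
                                  source_shape=(32, 32))
        out = decode(latent, random_weights)
        np.testing.assert_allclose(out, out[0, 0], atol=1e-6)

    def test_channel_mismatch_rejected(self, random_weights):
        latent = lg.LatentFeature(values=np.zeros((7, 8, 8),
                                                  dtype=np.float32),
                                  source_shape=(32, 32))
        with pytest.raises(ConfigurationError):
            decode(latent, random_weights)


class TestMixingIdentity:
    def test_self_mix_decodes_identically(self, random_weights, rng):
        img = rng.uniform(size=(32, 32))
        f = encode(img, random_weights)
        mixed = lg.mix_features(f, f)
        assert np.array_equal(mixed.values, f.values)
        assert np.array_equal(decode(mixed, random_weights),
                              decode(f, random_weights))

    def test_mix_with_zero_halves(self, random_weights, rng):
        f = encode(rng.uniform(size=(32, 32)), random_weights)
        zero = lg.LatentFeature(values=np.zeros_like(f.values),
                                source_shape=f.source_shape)
        mixed = lg.mix_features(f, zero)
        np.testing.assert_allclose(mixed.values, f.values / 2)

    def test_elementwise_mean_oracle(self, rng):
        a = lg.LatentFeature(values=rng.normal(size=(4, 5, 5))
                             .astype(np.float32), source_shape=(20, 20))
        b = lg.LatentFeature(values=rng.normal(size=(4, 5, 5))
                             .astype(np.float32), source_shape=(20, 20))
        got = lg.mix_features(a, b).values
        expected = np.empty_like(got)
        for idx in np.ndindex(got.shape):
            expected[idx] = (a.values[idx] + b.values[idx]) / 2
        np.testing.assert_array_equal(got, expected)


class TestWeightsIO:
    def test_save_load_round_trip(self, tmp_path, random_weights):
        path = tmp_path / "weights.npz"
        lg.save_weights(random_weights, path)
        back = lg.load_weights(path)
        for a, b in zip(random_weights.state_dict().items(),
                        back.state_dict().items()):
            assert a[0] == b[0]
            assert np.array_equal(a[1], b[1])

    def test_wrong_depth_names_offending_layer(self, tmp_path,
                                               random_weights):
        path = tmp_path / "weights.npz"
        lg.save_weights(random_weights, path)
        with pytest.raises(ConfigurationError, match="conv"):
            lg.load_weights(path, spec=AutoencoderSpec(depth_blocks=2,
                                                       width_divisor=8))

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(InputError):
            lg.load_weights(tmp_path / "absent.npz")

    def test_external_weights_with_matching_shapes_load(self, tmp_path):
        # any array set with matching layer names and shapes is accepted
        spec = AutoencoderSpec(3, 8)
        donor = AutoencoderWeights(spec, seed=7)
        path = tmp_path / "donor.npz"
        lg.save_weights(donor, path)
        loaded = lg.load_weights(path)
        assert loaded.spec == spec


class TestFixtureTraining:
    def test_seeded_training_reproducible_and_descending(self):
        corpus = lg.generate_texture_corpus(12, size=(32, 32), seed=0)
        w1 = lg.train_fixture_autoencoder(corpus, epochs=2, seed=0)
        w2 = lg.train_fixture_autoencoder(corpus, epochs=2, seed=0)
        for (k1, v1), (k2, v2) in zip(w1.state_dict().items(),
                                      w2.state_dict().items()):
            assert k1 == k2 and np.array_equal(v1, v2)
        losses = w1.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(InputError):
            lg.train_fixture_autoencoder([], epochs=1, seed=0)


def test_trained_fixture_beats_constant_predictor(fixture_weights):
    sample = lg.generate_phantom(lg.single_organ_config((128, 128)), seed=99)
    img = sample.image
    recon_err = np.abs(lg.reconstruct(img, fixture_weights) - img).mean()
    baseline = np.abs(img - img.mean()).mean()
    assert recon_err < baseline


def test_heldout_error_improves_across_checkpoints():
    corpus = lg.generate_texture_corpus(40, size=(64, 64), seed=0)
    heldout = lg.generate_texture_corpus(6, size=(64, 64), seed=1)
    w = lg.train_fixture_autoencoder(corpus, epochs=6, seed=0,
                                     eval_corpus=heldout)
    evals = w.history["eval_loss"]
    assert evals[-1] < evals[0]
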