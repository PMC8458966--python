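import numpy as np
import pytest

from longimpute import nn
from longimpute.errors import CheckpointError, ConfigError, ShapeError
from longimpute.networks import (
    DiscriminatorSpec,
    FeatureExtractorSpec,
    GeneratorSpec,
    TABLE1_DECODER,
    TABLE1_DISCRIMINATOR,
    TABLE1_ENCODER,
    TABLE1_FEATURE_BLOCKS,
    build_discriminator,
    build_feature_extractor,
    build_generator,
    load_bundle,
    make_bundle,
    save_bundle,
    scaled_channels,
)

SMALL_GEN = dict(encoder_channels=scaled_channels(TABLE1_ENCODER, 8),
                 decoder_channels=scaled_channels(TABLE1_DECODER, 8))
SMALL_DISC = DiscriminatorSpec(channels=scaled_channels(TABLE1_DISCRIMINATOR, 8))
SMALL_FEAT = FeatureExtractorSpec(
    block_channels=tuple(tuple(scaled_channels(b, 8)) for b in TABLE1_FEATURE_BLOCKS))


def _expected_generator_params(spec: GeneratorSpec) -> int:
    """Independent shape arithmetic: conv params = cout*cin*k^3 + cout."""
    e, d = spec.encoder_channels, spec.decoder_channels
    convs = []
    cin = spec.in_contrasts
    for cout in e:
        convs.append((cin, cout, 3))
        cin = cout
    skips = (e[1], e[3], e[5])
    decoder = [(e[7] + skips[2], d[0], 3), (d[0], d[1], 3),
               (d[1] + skips[1], d[2], 3), (d[2], d[3], 3),
               (d[3] + skips[0], d[4], 3), (d[4], d[5], 3), (d[5], 1, 1)]
    total_dec = sum(ci * co * k ** 3 + co for ci, co, k in decoder)
    total_enc = sum(ci * co * k ** 3 + co for ci, co, k in convs)
    return total_enc + spec.out_decoders * total_dec


class TestGenerator:
    def test_preserves_32cubed_shape_with_tanh_range(self, rng):
        g = build_generator(GeneratorSpec(**SMALL_GEN), seed=3)
        x = rng.normal(0, 0.5, (1, 32, 32, 32)).astype(np.float32)
        y = g.forward(x)
        assert y.shape == (1, 32, 32, 32)
        assert -1.0 < y.min() and y.max() < 1.0

    def test_all_zero_input_stays_inside_tanh_bounds(self):
        g = build_generator(GeneratorSpec(**SMALL_GEN), seed=3)
        y = g.forward(np.zeros((1, 16, 16, 16), dtype=np.float32))
        assert -1.0 < y.min() and y.max() < 1.0

    def test_rejects_axes_not_divisible_by_8(self):
        g = build_generator(GeneratorSpec(**SMALL_GEN), seed=0)
        with pytest.raises(ShapeError):
            g.forward(np.zeros((1, 20, 16, 16), dtype=np.float32))

    def test_rejects_wrong_contrast_count(self):
        g = build_generator(GeneratorSpec(**SMALL_GEN), seed=0)
        with pytest.raises(ShapeError):
            g.forward(np.zeros((2, 16, 16, 16), dtype=np.float32))

    def test_dual_decoder_outputs_and_independence(self, rng):
        g = build_generator(GeneratorSpec(in_contrasts=2, out_decoders=2, **SMALL_GEN),
                            seed=4)
        x = rng.normal(0, 0.5, (2, 16, 16, 16)).astype(np.float32)
        y1, y2 = g.forward(x)
        assert y1.shape == y2.shape == (1, 16, 16, 16)
        # perturbation probe: zeroing decoder-2 parameters changes output 2 only
        for p in g.decoders[1].params():
            p.value[...] = 0.0
        z1, z2 = g.forward(x)
        assert np.array_equal(z1, y1)
        assert not np.array_equal(z2, y2)

    def test_shared_encoder_is_one_object(self):
        g = build_generator(GeneratorSpec(in_contrasts=2, out_decoders=2, **SMALL_GEN),
                            seed=4)
        v1, v2 = g.views
        assert v1.encoder is v2.encoder
        p1 = v1.encoder.params()[0]
        p1.value[...] += 1.0
        assert np.array_equal(v2.encoder.params()[0].value, p1.value)

    def test_parameter_count_matches_shape_arithmetic(self):
        for spec in (GeneratorSpec(),  # published widths
                     GeneratorSpec(in_contrasts=2, out_decoders=2),
                     GeneratorSpec(in_contrasts=2, out_decoders=2, **SMALL_GEN)):
            g = build_generator(spec, seed=0)
            assert nn.parameter_count(g.params()) == _expected_generator_params(spec)

    def test_circular_padding_gives_exact_shift_equivariance(self, rng):
        """Translating by one full downsampling period (8 voxels) translates
        the output identically when boundary effects are removed."""
        g = build_generator(GeneratorSpec(pad_mode="circular", **SMALL_GEN), seed=5)
        x = rng.normal(0, 0.5, (1, 16, 16, 16)).astype(np.float32)
        y = g.forward(x)
        y_shift = g.forward(np.roll(x, 8, axis=1))
        assert np.allclose(np.roll(y, 8, axis=1), y_shift, atol=1e-4)

    def test_zero_padding_equivariance_holds_approximately_in_center(self, rng):
        g = build_generator(GeneratorSpec(norm=False, **SMALL_GEN), seed=5)
        x = np.zeros((1, 32, 16, 16), dtype=np.float32)
        x[:, 8:16, 4:12, 4:12] = rng.normal(0, 0.5, (8, 8, 8)).astype(np.float32)
        y = g.forward(x)
        y_shift = g.forward(np.roll(x, 8, axis=1))
        center = np.roll(y, 8, axis=1)[:, 12:20, 6:10, 6:10]
        assert np.allclose(center, y_shift[:, 12:20, 6:10, 6:10], atol=1e-2)


class TestDiscriminator:
    def test_score_map_shapes(self, rng):
        d = build_discriminator(SMALL_DISC, seed=1)
        for size, expect in ((32, 2), (64, 4)):
            s = d.forward(rng.normal(size=(size,) * 3).astype(np.float32))
            assert s.shape == (expect,) * 3

    def test_scores_strictly_inside_unit_interval(self, rng):
        d = build_discriminator(SMALL_DISC, seed=1)
        s = d.forward(rng.normal(size=(16, 16, 16)).astype(np.float32))
        assert 0.0 < s.min() and s.max() < 1.0

    def test_rejects_small_inputs(self):
        d = build_discriminator(SMALL_DISC, seed=1)
        with pytest.raises(ShapeError):
            d.forward(np.zeros((8, 8, 8), dtype=np.float32))


class TestFeatureExtractor:
    def test_phi1_shape(self, rng):
        f = build_feature_extractor(FeatureExtractorSpec(), seed=2)
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        assert f.features(x, 1).shape == (64, 16, 16, 16)

    def test_phi4_shape(self, rng):
        f = build_feature_extractor(FeatureExtractorSpec(), seed=2)
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        assert f.features(x, 4).shape == (512, 4, 4, 4)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        f1 = build_feature_extractor(SMALL_FEAT, seed=9)
        f2 = build_feature_extractor(SMALL_FEAT, seed=9)
        assert np.array_equal(f1.features(x, 2), f2.features(x, 2))
        assert np.array_equal(f1.features(x, 2), f1.features(x.copy(), 2))

    def test_pre_pool_indexing_option(self, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        import dataclasses

        f = build_feature_extractor(dataclasses.replace(SMALL_FEAT, phi_after_pool=False),
                                    seed=9)
        # pre-pool phi_1 keeps full resolution
        assert f.features(x, 1).shape[1:] == (16, 16, 16)

    def test_weight_file_round_trip_and_mismatch(self, tmp_path, rng):
        f = build_feature_extractor(SMALL_FEAT, seed=1)
        p = f.save_weights(tmp_path / "phi.npz")
        g = build_feature_extractor(SMALL_FEAT, seed=2)
        g.load_weights(p)
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        assert np.array_equal(f.features(x, 3), g.features(x, 3))
        with pytest.raises(CheckpointError):
            build_feature_extractor(FeatureExtractorSpec(), seed=0).load_weights(p)


class TestBundleCheckpoint:
    def _small_bundle(self, seed=0):
        return make_bundle(GeneratorSpec(in_contrasts=2, out_decoders=2, **SMALL_GEN),
                           SMALL_DISC, SMALL_FEAT, seed=seed,
                           contrasts_out=("T1w", "T2w"))

    def test_round_trip(self, tmp_path, rng):
        b = self._small_bundle(seed=3)
        p = save_bundle(b, tmp_path / "ckpt.npz")
        b2 = self._small_bundle(seed=99)
        load_bundle(p, b2)
        x = rng.normal(0, 0.5, (2, 16, 16, 16)).astype(np.float32)
        ya = b.generator.forward(x)
        yb = b2.generator.forward(x)
        assert np.array_equal(ya[0], yb[0]) and np.array_equal(ya[1], yb[1])

    def test_fingerprint_mismatch_refused(self, tmp_path):
        b = self._small_bundle()
        p = save_bundle(b, tmp_path / "ckpt.npz")
        other = make_bundle(GeneratorSpec(**SMALL_GEN), SMALL_DISC, SMALL_FEAT)
        with pytest.raises(CheckpointError):
            load_bundle(p, other)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorSpec(encoder_channels=(8, 8, 8))
        with pytest.raises(ConfigError):
            DiscriminatorSpec(channels=(8, 8))
        with pytest.raises(ConfigError):
            FeatureExtractorSpec(block_channels=((1, 2), (2, 3)))
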