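"""Regression CNN, latent mappers and end-to-end synthesis."""

import numpy as np
import pytest

from valvesynth import prediction as pred
from valvesynth import representation as rep
from valvesynth.preprocess import LEAFLET_TYPES


class TestRegressorSpec:
    def test_optimal_spec_shape_trace(self):
        spec = pred.OPTIMAL_REGRESSOR_SPEC
        assert (spec.blocks, spec.convs_per_block, spec.filters) == (4, 3, 16)
        assert (spec.dense_layers, spec.dense_units) == (1, 100)
        assert spec.pooled_shape == (2, 8, 8)
        assert spec.output_dim == 20

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            pred.RegressorSpec(blocks=6, convs_per_block=1, filters=4,
                               dense_layers=1, dense_units=10, output_dim=5)

    def test_cnn_forward_output_dim(self, volume_stack):
        spec = pred.RegressorSpec(blocks=4, convs_per_block=1, filters=4,
                                  dense_layers=1, dense_units=16, output_dim=20)
        cnn = pred.build_regression_cnn(spec, seed=0)
        out = cnn.forward(volume_stack[:2][..., None])
        assert out.shape == (2, 20)
        assert np.all(np.isfinite(out))


class TestMapperSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            pred.MapperSpec("svm")
        with pytest.raises(ValueError):
            pred.MapperSpec("rf", trees=0)
        with pytest.raises(ValueError):
            pred.MapperSpec("mlp", hidden_layers=0)
        assert pred.OPTIMAL_RF_SPEC.trees == 200
        assert (pred.OPTIMAL_MLP_SPEC.hidden_layers,
                pred.OPTIMAL_MLP_SPEC.hidden_units) == (4, 100)


class TestDomainMapper:
    def test_paired_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="length"):
            pred.fit_domain_mapper(pred.MapperSpec("rf", trees=5),
                                   rng.random((6, 4)), rng.random((5, 3)))

    def test_rf_constant_targets_predict_constant(self, rng):
        z_us = rng.random((10, 4))
        z_lf = np.tile([1.0, -2.0, 3.0], (10, 1))
        mapper = pred.fit_domain_mapper(pred.MapperSpec("rf", trees=20), z_us, z_lf)
        out = pred.map_latent(mapper, rng.random((5, 4)))
        assert np.allclose(out, z_lf[0])

    def test_rf_predictions_bounded_by_training_targets(self, rng):
        z_us = rng.standard_normal((30, 6))
        z_lf = rng.standard_normal((30, 5)) * 3
        mapper = pred.fit_domain_mapper(pred.MapperSpec("rf", trees=25, seed=1),
                                        z_us, z_lf)
        out = pred.map_latent(mapper, rng.standard_normal((40, 6)) * 5)
        for d in range(5):
            assert out[:, d].min() >= z_lf[:, d].min() - 1e-9
            assert out[:, d].max() <= z_lf[:, d].max() + 1e-9

    def test_mlp_recovers_noiseless_linear_map(self, rng):
        """With ample data and zero noise the mapper error is far below the
        target spread."""
        A = rng.standard_normal((6, 4))
        z_us = rng.standard_normal((400, 6))
        z_lf = z_us @ A
        mapper = pred.fit_domain_mapper(pred.MapperSpec("mlp", hidden_layers=2,
                                                        hidden_units=50, seed=0),
                                        z_us, z_lf)
        z_test = rng.standard_normal((100, 6))
        err = np.sqrt(np.mean((pred.map_latent(mapper, z_test) - z_test @ A) ** 2))
        assert err < 0.2 * z_lf.std()

    def test_dimension_mismatch_on_predict(self, rng):
        mapper = pred.fit_domain_mapper(pred.MapperSpec("rf", trees=5),
                                        rng.random((8, 4)), rng.random((8, 3)))
        with pytest.raises(ValueError, match="length"):
            pred.map_latent(mapper, rng.random((2, 7)))

    def test_batch_order_preserved(self, rng):
        mapper = pred.fit_domain_mapper(pred.MapperSpec("rf", trees=10, seed=0),
                                        rng.random((20, 4)), rng.random((20, 3)))
        batch = rng.random((6, 4))
        full = pred.map_latent(mapper, batch)
        singles = np.concatenate([pred.map_latent(mapper, batch[i:i + 1])
                                  for i in range(6)])
        assert np.array_equal(full, singles)


@pytest.fixture(scope="module")
def domain_pipeline(tiny_leaflet_ae, small_dataset, volume_stack):
    us_ae = rep.build_autoencoder(rep.AutoencoderSpec("3d", 4, 8, 12), seed=1)
    rep.train_autoencoder(us_ae, volume_stack,
                          rep.TrainConfig(epochs=1, batch_size=8, seed=1))
    by_type = {lt: np.stack([r.leaflets[lt].pixels for r in small_dataset])
               for lt in LEAFLET_TYPES}
    return pred.train_domain_pipeline(tiny_leaflet_ae, us_ae,
                                      pred.MapperSpec("rf", trees=20, seed=2),
                                      volume_stack, by_type)


class TestSynthesis:
    def test_synthesize_contract(self, domain_pipeline, small_dataset):
        vol = small_dataset[0].volume
        images = pred.synthesize(domain_pipeline, vol)
        assert set(images) == set(LEAFLET_TYPES)
        for lt, img in images.items():
            assert img.pixels.shape == (128, 64)
            assert img.pixels.min() >= 0 and img.pixels.max() <= 1
            assert img.leaflet_type == lt

    def test_identical_volumes_identical_outputs(self, domain_pipeline, small_dataset):
        vol = small_dataset[1].volume
        a = pred.synthesize(domain_pipeline, vol)
        b = pred.synthesize(domain_pipeline, vol)
        for lt in LEAFLET_TYPES:
            assert np.array_equal(a[lt].pixels, b[lt].pixels)

    def test_untrained_components_are_named(self, tiny_leaflet_ae, small_dataset):
        pipe = pred.SynthesisPipeline(method="domain_rf", leaflet_ae=tiny_leaflet_ae)
        with pytest.raises(RuntimeError, match="predictor"):
            pred.synthesize(pipe, small_dataset[0].volume)
        with pytest.raises(ValueError):
            pred.SynthesisPipeline(method="nonsense", leaflet_ae=tiny_leaflet_ae)

    def test_missing_leaflet_type_rejected(self, tiny_leaflet_ae, volume_stack,
                                           small_dataset):
        by_type = {"rc": np.stack([r.leaflets["rc"].pixels for r in small_dataset])}
        with pytest.raises(ValueError, match="lc"):
            pred.train_shape_estimator(
                tiny_leaflet_ae,
                pred.RegressorSpec(blocks=4, convs_per_block=1, filters=2,
                                   dense_layers=1, dense_units=8, output_dim=20),
                volume_stack, by_type, rep.TrainConfig(epochs=1, seed=0))


class TestShapeEstimator:
    def test_training_bookkeeping_and_independence(self, tiny_leaflet_ae,
                                                   small_dataset, volume_stack):
        """Each type gets its own regressor; rc retraining leaves lc alone."""
        spec = pred.RegressorSpec(blocks=4, convs_per_block=1, filters=2,
                                  dense_layers=1, dense_units=8, output_dim=20)
        by_type = {lt: np.stack([r.leaflets[lt].pixels for r in small_dataset])
                   for lt in LEAFLET_TYPES}
        cfg = rep.TrainConfig(epochs=1, batch_size=8, seed=5)
        pipe = pred.train_shape_estimator(tiny_leaflet_ae, spec, volume_stack,
                                          by_type, cfg)
        assert set(pipe.predictors) == set(LEAFLET_TYPES)
        codes_before = pred.predict_codes(pipe, volume_stack[:2])
        # retrain only rc with a different seed
        pipe.predictors["rc"] = pred.train_shape_estimator(
            tiny_leaflet_ae, spec, volume_stack, {"rc": by_type["rc"]},
            rep.TrainConfig(epochs=1, batch_size=8, seed=99),
            types=("rc",)).predictors["rc"]
        codes_after = pred.predict_codes(pipe, volume_stack[:2])
        assert not np.array_equal(codes_before["rc"], codes_after["rc"])
        assert np.array_equal(codes_before["lc"], codes_after["lc"])
        assert np.array_equal(codes_before["nc"], codes_after["nc"])

    def test_requires_trained_leaflet_ae(self, volume_stack, small_dataset):
        untrained = rep.build_autoencoder(rep.OPTIMAL_LEAFLET_SPEC, seed=0)
        by_type = {lt: np.stack([r.leaflets[lt].pixels for r in small_dataset])
                   for lt in LEAFLET_TYPES}
        with pytest.raises(RuntimeError, match="autoencoder"):
            pred.train_shape_estimator(untrained, pred.OPTIMAL_REGRESSOR_SPEC,
                                       volume_stack, by_type)


def test_pipeline_persistence_roundtrip(tmp_path, domain_pipeline, small_dataset):
    from valvesynth.persistence import load_pipeline, save_pipeline

    save_pipeline(domain_pipeline, tmp_path / "pipe")
    back = load_pipeline(tmp_path / "pipe")
    vol = small_dataset[2].volume
    a = pred.synthesize(domain_pipeline, vol)
    b = pred.synthesize(back, vol)
    for lt in LEAFLET_TYPES:
        assert np.allclose(a[lt].pixels, b[lt].pixels, atol=1e-6)
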