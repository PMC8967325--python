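"""Crossvalidation plans, grid search and the performance harness."""

import numpy as np
import pandas as pd
import pytest

from valvesynth import evaluation as ev
from valvesynth import representation as rep
from valvesynth.prediction import MapperSpec


class TestMonteCarloSplit:
    def test_test_size_rounding(self):
        plan29 = ev.monte_carlo_split([f"v{i}" for i in range(29)], n_folds=3, seed=0)
        for train, test in plan29.folds:
            assert len(test) == 6 and len(train) == 23  # round(0.2 * 29)
        plan10 = ev.monte_carlo_split([f"v{i}" for i in range(10)], n_folds=2, seed=0)
        for train, test in plan10.folds:
            assert len(test) == 2 and len(train) == 8

    def test_partition_within_fold_and_determinism(self):
        ids = [f"v{i}" for i in range(17)]
        p1 = ev.monte_carlo_split(ids, n_folds=5, seed=42)
        p2 = ev.monte_carlo_split(ids, n_folds=5, seed=42)
        assert p1 == p2
        for train, test in p1.folds:
            assert set(train) & set(test) == set()
            assert set(train) | set(test) == set(ids)
        p3 = ev.monte_carlo_split(ids, n_folds=5, seed=43)
        assert p3 != p1

    def test_folds_are_independent_draws(self):
        plan = ev.monte_carlo_split([f"v{i}" for i in range(30)], n_folds=8, seed=1)
        tests = {fold[1] for fold in plan.folds}
        assert len(tests) > 1  # overwhelmingly likely for independent draws

    def test_too_few_ids(self):
        with pytest.raises(ValueError, match="at least 5"):
            ev.monte_carlo_split(["a", "b", "c"], n_folds=2, seed=0)


QUICK_2D = rep.TrainConfig(epochs=2, batch_size=8, seed=0)


class TestGridSearchAutoencoder:
    def test_smoke_grid_selects_minimal_mean(self, leaflet_stack):
        grid = [rep.AutoencoderSpec("2d", 3, 4, 8),
                rep.AutoencoderSpec("2d", 3, 4, 16)]
        result = ev.grid_search_autoencoder(grid, leaflet_stack, n_folds=2,
                                            seed=0, config=QUICK_2D)
        assert len(result.table) == 2
        best_row = result.table.loc[result.table["mean"].idxmin()]
        assert result.best == best_row["spec"]

    def test_aux_images_only_augment_training(self, leaflet_stack):
        """Scores are computed on held-out originals; aux size never shrinks
        the test fold."""
        aux = np.zeros((5, 128, 64), dtype=np.float32)
        grid = [rep.AutoencoderSpec("2d", 3, 4, 8)]
        r_noaux = ev.grid_search_autoencoder(grid, leaflet_stack[:12], n_folds=2,
                                             seed=1, config=QUICK_2D)
        r_aux = ev.grid_search_autoencoder(grid, leaflet_stack[:12], n_folds=2,
                                           seed=1, config=QUICK_2D, aux_images=aux)
        assert len(r_aux.table) == len(r_noaux.table) == 1  # same fold structure

    def test_empty_or_invalid_grid(self, leaflet_stack):
        with pytest.raises(ValueError, match="empty"):
            ev.grid_search_autoencoder([], leaflet_stack)

    def test_reproducible_best(self, leaflet_stack):
        grid = [rep.AutoencoderSpec("2d", 3, 4, 4),
                rep.AutoencoderSpec("2d", 4, 4, 4)]
        b1 = ev.grid_search_autoencoder(grid, leaflet_stack[:9], n_folds=2,
                                        seed=5, config=QUICK_2D).best
        b2 = ev.grid_search_autoencoder(grid, leaflet_stack[:9], n_folds=2,
                                        seed=5, config=QUICK_2D).best
        assert b1 == b2


def test_table_grid_sizes():
    """The three published hyperparameter grids have 18, 162 and 18+25 points."""
    leaflet_grid = [(nc, nf, nl) for nc in (3, 4, 5) for nf in (16, 32)
                    for nl in (10, 20, 30)]
    assert len(leaflet_grid) == 18
    cnn_grid = [(kb, kc, kf, kd, kn) for kb in (3, 4, 5) for kc in (1, 2, 3)
                for kf in (16, 32) for kd in (1, 2, 3) for kn in (50, 100, 200)]
    assert len(cnn_grid) == 162
    us_grid = [(mc, mf, ml) for mc in (3, 4, 5) for mf in (16, 32)
               for ml in (20, 100, 200)]
    assert len(us_grid) == 18
    rf_grid = [50, 100, 150, 200, 250]
    mlp_grid = [(lh, ln) for lh in (1, 2, 3, 4, 5) for ln in (50, 100, 150, 200)]
    assert len(rf_grid) == 5 and len(mlp_grid) == 20


class TestGridSearchPredictor:
    def test_mapper_grid_smoke(self, small_dataset):
        cfg = ev.ExperimentConfig(
            us_spec=rep.AutoencoderSpec("3d", 4, 4, 8),
            leaflet_train=QUICK_2D,
            us_train=rep.TrainConfig(epochs=1, batch_size=8, seed=1))
        grid = [MapperSpec("rf", trees=5, seed=0), MapperSpec("rf", trees=10, seed=0)]
        result = ev.grid_search_predictor(grid, small_dataset, config=cfg,
                                          n_folds=2, seed=0)
        assert len(result.table) == 2
        assert np.isfinite(result.table["mean"]).all()
        assert result.best in grid

    def test_output_dim_validated_before_training(self, small_dataset):
        from valvesynth.prediction import RegressorSpec

        bad = RegressorSpec(blocks=4, convs_per_block=1, filters=2,
                            dense_layers=1, dense_units=8, output_dim=7)
        with pytest.raises(ValueError, match="latent dim"):
            ev.grid_search_predictor([bad], small_dataset, n_folds=2, seed=0)


class TestDistributionSummary:
    def _features(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(12):
            true_len = rng.uniform(80, 110)
            for src, val in (("true", true_len), ("mlp", true_len + rng.normal(0, 2))):
                rows.append({"source": src, "valve_id": f"v{i}", "leaflet_type": "rc",
                             "length": val, "width": val / 2, "area": val * 30})
        return pd.DataFrame(rows)

    def test_summary_and_correlations(self):
        feats = self._features()
        summary, corr = ev.distribution_summary(feats)
        assert ("rc", "true") in summary.index
        r = corr.loc[(corr["source"] == "mlp") & (corr["feature"] == "length"),
                     "pearson_r"].item()
        assert 0.9 < r <= 1.0

    def test_perfect_prediction_and_constant_feature(self):
        feats = self._features()
        perfect = feats[feats["source"] == "true"].copy()
        perfect["source"] = "copy"
        summary, corr = ev.distribution_summary(pd.concat([feats, perfect]))
        r = corr.loc[(corr["source"] == "copy") & (corr["feature"] == "length"),
                     "pearson_r"].item()
        assert r == pytest.approx(1.0)
        const = feats.copy()
        const["width"] = 5.0
        summary_c, _ = ev.distribution_summary(const)
        assert summary_c.loc[("rc", "true"), "width_var"] == 0.0

    def test_correlation_invariant_to_unit_scaling(self):
        feats = self._features()
        scaled = feats.copy()
        scaled[["length", "width", "area"]] *= 0.34
        _, c1 = ev.distribution_summary(feats)
        _, c2 = ev.distribution_summary(scaled)
        assert np.allclose(c1["pearson_r"], c2["pearson_r"])


class TestTsne:
    def test_embedding_contract_and_determinism(self, rng):
        codes = rng.standard_normal((30, 20))
        a = ev.tsne_embed(codes, seed=3)
        b = ev.tsne_embed(codes, seed=3)
        assert a.shape == (30, 2)
        assert np.array_equal(a, b)

    def test_duplicated_codes_land_close(self, rng):
        base = rng.standard_normal((20, 10)) * 5
        codes = np.concatenate([base, base[:1] + 1e-9])
        emb = ev.tsne_embed(codes, seed=0)
        from scipy.spatial.distance import pdist

        dup_dist = np.linalg.norm(emb[0] - emb[-1])
        assert dup_dist < np.median(pdist(emb))

    def test_too_few_codes(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            ev.tsne_embed(rng.standard_normal((3, 8)), seed=0)


@pytest.fixture(scope="module")
def quick_report(small_dataset):
    cfg = ev.ExperimentConfig(
        us_spec=rep.AutoencoderSpec("3d", 4, 4, 8),
        leaflet_train=rep.TrainConfig(epochs=8, batch_size=8, seed=0),
        us_train=rep.TrainConfig(epochs=1, batch_size=8, seed=1))
    return ev.run_performance_analysis(
        small_dataset, methods=("reconstruction", "mean_baseline", "domain_rf"),
        n_folds=2, seed=0, config=cfg)


class TestPerformanceAnalysis:
    def test_row_bookkeeping(self, quick_report):
        frame = quick_report.frame
        # 3 leaflet types x 3 methods x 2 folds x 2 test valves
        assert len(frame) == 3 * 3 * 2 * 2
        assert set(frame["method"]) == {"reconstruction", "mean_baseline", "domain_rf"}
        agg = quick_report.aggregate()
        assert ("rmse", "mean") in agg.columns

    def test_aggregate_recomputes_from_rows(self, quick_report):
        agg = quick_report.aggregate()
        frame = quick_report.frame
        manual = frame[frame["method"] == "mean_baseline"]["ascd_px"].mean()
        assert agg.loc["mean_baseline", ("ascd_px", "mean")] == pytest.approx(manual)

    def test_reconstruction_beats_predictions_on_jaccard(self, quick_report):
        agg = quick_report.aggregate()
        rec = agg.loc["reconstruction", ("jaccard", "mean")]
        assert rec >= agg.loc["mean_baseline", ("jaccard", "mean")]
        assert rec >= agg.loc["domain_rf", ("jaccard", "mean")]

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown"):
            ev.run_performance_analysis(small_dataset, methods=("gan",), n_folds=2)
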