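"""The paired synthetic-valve generator: geometry, determinism, coupling."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from valvesynth import features as F
from valvesynth import synthetic as syn
from valvesynth.preprocess import LEAFLET_TYPES


RES = 0.34  # mm per pixel of the rendered leaflet images


class TestRenderLeaflet:
    def test_measured_extents_match_parameters(self):
        p = syn.LeafletParams(width=16.0, height=32.0, belly_curvature=0.6,
                              asymmetry=0.1, leaflet_type="lc")
        img = syn.render_leaflet(p)
        sf = F.shape_features(img)
        assert sf.width_px == pytest.approx(p.width / RES, abs=1.5)
        assert sf.length_px == pytest.approx(p.height / RES, abs=1.5)

    def test_zero_belly_gives_triangle_area(self):
        p = syn.LeafletParams(width=12.0, height=30.0, belly_curvature=0.0)
        area = F.shape_features(syn.render_leaflet(p)).area_px
        expected = 0.5 * (p.width / RES) * (p.height / RES)
        assert area == pytest.approx(expected, rel=0.03)

    def test_full_belly_gives_half_ellipse_area(self):
        p = syn.LeafletParams(width=14.0, height=30.0, belly_curvature=1.0)
        area = F.shape_features(syn.render_leaflet(p)).area_px
        expected = 0.25 * np.pi * (p.width / RES) * (p.height / RES)
        assert area == pytest.approx(expected, rel=0.03)

    def test_symmetric_leaflet_mirrors_about_mid_row(self):
        p = syn.LeafletParams(width=14.0, height=30.0, belly_curvature=0.7,
                              asymmetry=0.0)
        img = syn.render_leaflet(p).pixels
        assert np.abs(img - img[::-1, :]).max() <= 1 / 255

    def test_interior_intensity_band_and_zero_background(self):
        p = syn.LeafletParams(width=14.0, height=30.0, belly_curvature=0.5)
        img = syn.render_leaflet(p, supersample=1).pixels  # no edge averaging
        inside = img > 0
        assert img[inside].min() > 0.6 and img[inside].max() <= 1.0
        assert np.mean(img == 0) > 0.3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            syn.LeafletParams(width=-1, height=30, belly_curvature=0.5)
        with pytest.raises(ValueError):
            syn.LeafletParams(width=14, height=30, belly_curvature=1.5)
        with pytest.raises(ValueError):
            syn.LeafletParams(width=14, height=50, belly_curvature=0.5)  # too tall


class TestRenderRootVolume:
    def test_noiseless_ring_and_field_mask(self):
        p = syn.RootParams(annulus_radius=11.0, speckle_sigma=0.0)
        vol = syn.render_root_volume(p).voxels
        assert vol.shape == (32, 128, 128)
        # voxels outside the circular imaging field are exactly zero
        rows = (np.arange(128) - 63.5) * 0.49
        cols = (np.arange(128) - 63.5) * 0.49
        outside = (rows[:, None] ** 2 + cols[None, :] ** 2) > (0.46 * 128 * 0.49) ** 2
        assert vol[:, outside].max() == 0.0
        assert vol.max() > 0.5  # the wall is bright

    def test_bright_voxel_count_monotone_in_radius(self):
        counts = []
        for r in np.linspace(8.0, 13.0, 5):
            p = syn.RootParams(annulus_radius=float(r), speckle_sigma=0.0)
            counts.append(int((syn.render_root_volume(p).voxels > 0).sum()))
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_same_seed_bit_identical(self):
        p = syn.RootParams(annulus_radius=11.0, speckle_sigma=0.05)
        a = syn.render_root_volume(p, noise_seed=3).voxels
        b = syn.render_root_volume(p, noise_seed=3).voxels
        assert np.array_equal(a, b)
        c = syn.render_root_volume(p, noise_seed=4).voxels
        assert not np.array_equal(a, c)

    def test_threshold_band_is_respected(self):
        p = syn.RootParams(annulus_radius=11.0, speckle_sigma=0.08)
        v = syn.render_root_volume(p, noise_seed=1).voxels
        assert not np.any((v > 0) & (v < 80 / 255))


class TestSamplingAndCoupling:
    def test_sample_valve_repeatable_and_complete(self):
        a = syn.sample_valve("v1", seed=11)
        b = syn.sample_valve("v1", seed=11)
        assert np.array_equal(a.volume.voxels, b.volume.voxels)
        assert set(a.leaflets) == set(LEAFLET_TYPES)
        for lt in LEAFLET_TYPES:
            assert np.array_equal(a.leaflets[lt].pixels, b.leaflets[lt].pixels)
            assert a.leaflet_params[lt] == b.leaflet_params[lt]

    def test_zero_noise_coupling_is_exact_linear(self):
        coupling = syn.CouplingModel(noise_sd_width=0.0, noise_sd_height=0.0)
        root = syn.RootParams(annulus_radius=11.0, root_height=23.0)
        rng = np.random.default_rng(0)
        lp = coupling.leaflet_params(root, "rc", rng)
        ow, oh = syn._TYPE_OFFSETS["rc"]
        assert lp.width == pytest.approx(0.9 * 11 + 0.12 * 23 + 0.1 + ow)
        assert lp.height == pytest.approx(1.6 * 11 + 0.45 * 23 + 1.0 + oh)

    def test_noiseless_coefficients_recoverable_by_regression(self):
        """Linear regression on (radius, height) recovers the coupling map."""
        coupling = syn.CouplingModel(noise_sd_width=0.0, noise_sd_height=0.0)
        rng = np.random.default_rng(5)
        prior = syn.RootPrior()
        roots = [prior.sample(rng) for _ in range(80)]
        X = np.array([[r.annulus_radius, r.root_height] for r in roots])
        yw = np.array([coupling.leaflet_params(r, "lc", rng).width for r in roots])
        fit = LinearRegression().fit(X, yw)
        assert fit.coef_[0] == pytest.approx(coupling.coef_width[0], rel=0.01)
        assert fit.coef_[1] == pytest.approx(coupling.coef_width[1], rel=0.01)

    def test_strong_coupling_r2_high_none_coupling_r2_null(self):
        records = syn.sample_dataset(60, "strong", seed=3)
        X = np.array([[r.root_params.annulus_radius, r.root_params.root_height]
                      for r in records])
        y = np.array([r.leaflet_params["rc"].height for r in records])
        r2_strong = LinearRegression().fit(X, y).score(X, y)
        assert r2_strong > 0.8
        records0 = syn.sample_dataset(60, "none", seed=3)
        X0 = np.array([[r.root_params.annulus_radius, r.root_params.root_height]
                       for r in records0])
        y0 = np.array([r.leaflet_params["rc"].height for r in records0])
        assert LinearRegression().fit(X0, y0).score(X0, y0) < 0.2

    def test_dataset_bookkeeping_and_determinism(self):
        ds = syn.sample_dataset(12, "strong", seed=9)
        assert len(ds) == 12
        assert len({r.valve_id for r in ds}) == 12
        truth = syn.truth_table(ds)
        assert len(truth) == 4 * 12  # one root + three leaflet rows per valve
        ds2 = syn.sample_dataset(12, "strong", seed=9)
        assert np.array_equal(ds[5].volume.voxels, ds2[5].volume.voxels)

    def test_rendered_records_pass_image_invariants(self, small_dataset):
        for rec in small_dataset[:3]:
            v = rec.volume.voxels
            assert v.shape == (32, 128, 128) and v.min() >= 0 and v.max() <= 1
            assert not np.any((v > 0) & (v < 80 / 255))
            for lt, img in rec.leaflets.items():
                px = img.pixels
                assert px.shape == (128, 64) and px.min() >= 0 and px.max() <= 1


def test_generate_benchmark_roundtrip(tmp_path):
    from valvesynth import io as vio

    manifest = syn.generate_benchmark(tmp_path, 10, "strong", seed=2)
    assert len(manifest) == 10
    loaded = vio.read_manifest(tmp_path / "manifest.csv")
    assert loaded.n_leaflet_images == 30
    records = vio.load_dataset(loaded)
    orig = syn.sample_dataset(10, "strong", seed=2)
    # PNG quantization bounds the leaflet round-trip error at half a gray level
    assert np.abs(records[0].leaflets["rc"].pixels
                  - orig[0].leaflets["rc"].pixels).max() <= 0.5 / 255 + 1e-6
    assert np.allclose(records[3].volume.voxels, orig[3].volume.voxels, atol=1e-6)
    with pytest.raises(ValueError):
        syn.generate_benchmark(tmp_path, 5, "strong", seed=2)  # too few valves
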