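"""Tests of the scene generator and SNR-controlled noise injection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import measure

from segpick import (
    CLASS_CARBON,
    CLASS_ICE,
    CLASS_PROTEIN,
    Micrograph,
    NoiseSpec,
    SceneSpec,
    add_gaussian_noise,
    add_poisson_noise,
    db_to_linear,
    linear_to_db,
    make_micrograph,
    measure_snr,
)


class TestMakeMicrograph:
    def test_component_and_center_counts(self):
        spec = SceneSpec(image_size=(128, 128), n_particles=10,
                         particle_radius_px=5, seed=0)
        mg, mask, particles = make_micrograph(spec)
        assert len(particles) == 10
        assert measure.label(mask.labels == CLASS_PROTEIN, connectivity=2).max() == 10

    def test_seeded_determinism(self):
        spec = SceneSpec(image_size=(96, 96), n_particles=6, seed=9)
        a = make_micrograph(spec)
        b = make_micrograph(spec)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].labels, b[1].labels)
        assert np.array_equal(a[2].centers, b[2].centers)

    def test_carbon_edge_band(self):
        spec = SceneSpec(image_size=(100, 100), n_particles=0, carbon_edge=True, seed=1)
        _, mask, _ = make_micrograph(spec)
        band = mask.labels == CLASS_CARBON
        cols = np.nonzero(band.any(axis=0))[0]
        assert band[:, cols].all()  # contiguous full-height border band
        assert cols[0] == 0

    def test_ice_blobs_labeled(self):
        spec = SceneSpec(image_size=(128, 128), n_particles=2, ice_blobs=2, seed=4)
        mg, mask, _ = make_micrograph(spec)
        assert (mask.labels == CLASS_ICE).sum() > 0
        assert mg.pixels[mask.labels == CLASS_ICE].mean() > mg.pixels.mean()

    def test_particles_darker_than_background(self):
        spec = SceneSpec(image_size=(96, 96), n_particles=5, particle_contrast=0.5, seed=2)
        mg, mask, _ = make_micrograph(spec)
        assert mg.pixels[mask.labels == CLASS_PROTEIN].mean() < \
            mg.pixels[mask.labels == 0].mean()

    def test_impossible_placement_raises(self):
        from segpick import PlacementError

        spec = SceneSpec(image_size=(64, 64), n_particles=50,
                         particle_radius_px=10, seed=0)
        with pytest.raises(PlacementError):
            make_micrograph(spec)


class TestDbConversions:
    @pytest.mark.parametrize("db,linear", [
        (0.8, 1.202), (-7.5, 0.1778), (-9.5, 0.1122), (-11, 0.0794),
        (-13, 0.0501), (-16, 0.0251), (-17.66, 0.0171),
    ])
    def test_decibel_linear_pairs(self, db, linear):
        assert db_to_linear(db) == pytest.approx(linear, abs=5e-4)

    def test_zero_db_is_unity(self):
        assert db_to_linear(0.0) == 1.0
        assert linear_to_db(1.0) == 0.0

    @settings(deadline=None, max_examples=40)
    @given(st.floats(-40, 40))
    def test_inverse_round_trip(self, db):
        assert linear_to_db(db_to_linear(db)) == pytest.approx(db, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            linear_to_db(0.0)


@pytest.fixture(scope="module")
def big_scene():
    spec = SceneSpec(image_size=(512, 512), n_particles=40,
                     particle_radius_px=10, seed=21)
    return make_micrograph(spec)[0]


class TestGaussianNoise:
    def test_snr_within_tolerance(self, big_scene):
        noisy = add_gaussian_noise(big_scene, NoiseSpec("gaussian", -9.5, seed=3))
        assert measure_snr(big_scene, noisy) == pytest.approx(-9.5, abs=0.3)

    def test_seeded_determinism(self, big_scene):
        a = add_gaussian_noise(big_scene, NoiseSpec("gaussian", 0.0, seed=5))
        b = add_gaussian_noise(big_scene, NoiseSpec("gaussian", 0.0, seed=5))
        assert np.array_equal(a.pixels, b.pixels)

    def test_high_snr_limit_vanishing_noise(self, big_scene):
        noisy = add_gaussian_noise(big_scene, NoiseSpec("gaussian", 120.0, seed=1))
        dev = np.abs(noisy.pixels - big_scene.pixels).max()
        assert dev < 1e-3 * big_scene.pixels.std()

    def test_constant_image_rejected(self):
        flat = Micrograph(np.full((32, 32), 1.0, dtype=np.float32))
        with pytest.raises(ValueError):
            add_gaussian_noise(flat, NoiseSpec("gaussian", 0.0, seed=0))


class TestPoissonNoise:
    def test_snr_within_tolerance(self, big_scene):
        noisy = add_poisson_noise(big_scene, NoiseSpec("poisson", -16.0, seed=3))
        assert measure_snr(big_scene, noisy) == pytest.approx(-16.0, abs=0.5)

    def test_seeded_determinism(self, big_scene):
        a = add_poisson_noise(big_scene, NoiseSpec("poisson", -5.0, seed=2))
        b = add_poisson_noise(big_scene, NoiseSpec("poisson", -5.0, seed=2))
        assert np.array_equal(a.pixels, b.pixels)

    def test_counts_nonnegative_before_rescale(self, big_scene):
        noisy = add_poisson_noise(big_scene, NoiseSpec("poisson", 0.0, seed=1))
        assert noisy.pixels.min() >= big_scene.pixels.min() - 1e-9

    def test_constant_image_rejected(self):
        flat = Micrograph(np.full((32, 32), 1.0, dtype=np.float32))
        with pytest.raises(ValueError):
            add_poisson_noise(flat, NoiseSpec("poisson", 0.0, seed=0))


class TestNoiseDegradesPicking:
    def test_ap_non_increasing_as_snr_drops(self):
        """A model trained on clean scenes picks monotonically worse as
        Gaussian noise rises (20 -> 0 -> -10 dB)."""
        import segpick as sp
        from segpick.evalmetrics import average_precision, pr_curve
        from segpick.pick import PickParams, pick_micrograph
        from segpick.segnet import FRRNConfig, TrainConfig, build_frrn, predict, train

        scenes = [sp.make_micrograph(sp.SceneSpec(
            image_size=(128, 128), n_particles=8, particle_radius_px=6,
            particle_contrast=0.5, seed=200 + i)) for i in range(3)]
        lp = sp.LabelParams(intensity_low=150, intensity_high=255,
                            min_area_px=40, max_area_px=2000)
        pairs = [(sp.compose_three_channel(mg), sp.generate_label(mg, lp))
                 for mg, _, _ in scenes]
        model = build_frrn(FRRNConfig(n_pooling_stages=2, n_unpooling_stages=2,
                                      base_channels=8), seed=0)
        model, _ = train(model, pairs, TrainConfig(epochs=50, seed=0, crop_size=128))
        params = PickParams(particle_radius_px=6, prob_threshold=0.5)
        aps = []
        for db in (20.0, 0.0, -10.0):
            ap_per_scene = []
            for mg, _, pts in scenes:
                noisy = sp.add_gaussian_noise(mg, NoiseSpec("gaussian", db, seed=3))
                prob = predict(model, sp.compose_three_channel(noisy))
                picked = pick_micrograph(prob, params)
                if len(picked) == 0:
                    ap_per_scene.append(0.0)
                    continue
                curve = pr_curve(picked, pts, 6.0, np.linspace(0.3, 0.9, 7))
                ap_per_scene.append(average_precision(curve))
            aps.append(float(np.mean(ap_per_scene)))
        assert aps[0] >= aps[1] >= aps[2]


class TestMeasureSnr:
    def test_unit_ratio_is_zero_db(self, big_scene, rng):
        noise = rng.normal(0, big_scene.pixels.std(), big_scene.pixels.shape)
        noisy = Micrograph((big_scene.pixels + noise).astype(np.float32))
        assert measure_snr(big_scene, noisy) == pytest.approx(0.0, abs=0.1)

    def test_identical_images_give_inf(self, big_scene):
        assert math.isinf(measure_snr(big_scene, big_scene))

    def test_doubling_noise_std_costs_six_db(self, big_scene, rng):
        sigma = big_scene.pixels.std()
        noise = rng.normal(0, 1.0, big_scene.pixels.shape)
        a = Micrograph((big_scene.pixels + sigma * noise).astype(np.float32))
        b = Micrograph((big_scene.pixels + 2 * sigma * noise).astype(np.float32))
        drop = measure_snr(big_scene, a) - measure_snr(big_scene, b)
        assert drop == pytest.approx(20 * math.log10(2), abs=0.2)

    def test_dimension_preservation(self, big_scene):
        noisy = add_gaussian_noise(big_scene, NoiseSpec("gaussian", 3.0, seed=0))
        assert noisy.pixels.shape == big_scene.pixels.shape
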