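"""Synthetic scene generator: spectra, scenes, dataset plumbing."""

import numpy as np
import pytest

from hsin.exceptions import InvalidInputError
from hsin.hsi_io import calibrate
from hsin.synth import (
    SceneSpec,
    TreatmentProfile,
    base_curve,
    default_profiles,
    default_swir_wavelengths,
    default_vnir_wavelengths,
    generate_dataset,
    generate_scene,
    generate_spectrum,
)

ALL_W = np.concatenate([default_vnir_wavelengths(), default_swir_wavelengths()])


class TestSpectrum:
    def test_zero_noise_equals_base_curve(self, quiet_profiles):
        p = quiet_profiles["HNHP"]
        out = generate_spectrum(p, ALL_W, np.random.default_rng(0))
        np.testing.assert_allclose(out, base_curve(p, ALL_W), atol=1e-12)

    def test_nir_plateau_ordering(self, profiles):
        """Healthy (HNHP) canopies out-reflect starved (LNLP) in the NIR."""
        rng = np.random.default_rng(3)
        nir = (ALL_W >= 750) & (ALL_W <= 1100)
        hi = generate_spectrum(profiles["HNHP"], ALL_W, rng)[nir].mean()
        lo = generate_spectrum(profiles["LNLP"], ALL_W, rng)[nir].mean()
        assert hi > lo

    def test_red_reflectance_ordering(self, quiet_profiles):
        """Low-N treatments reflect more in the 600-700 nm red region."""
        red = (ALL_W >= 600) & (ALL_W <= 700)
        means = {
            k: base_curve(p, ALL_W)[red].mean() for k, p in quiet_profiles.items()
        }
        assert min(means["LNHP"], means["LNLP"]) > max(means["HNHP"], means["HNLP"])

    def test_deterministic_given_seed(self, profiles):
        a = generate_spectrum(profiles["LNHP"], ALL_W, np.random.default_rng(42))
        b = generate_spectrum(profiles["LNHP"], ALL_W, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_range_and_green_peak_position(self, quiet_profiles):
        for p in quiet_profiles.values():
            r = base_curve(p, ALL_W)
            assert np.all((0 <= r) & (r <= 1))
            # local maximum in the green, before the red-edge rise begins
            vis = (ALL_W > 430) & (ALL_W < 680)
            peak_w = ALL_W[vis][np.argmax(r[vis])]
            assert 530 <= peak_w <= 570

    def test_empty_grid_rejected(self, profiles):
        with pytest.raises(InvalidInputError):
            generate_spectrum(profiles["HNHP"], np.array([]))

    def test_profile_parameter_validation(self):
        with pytest.raises(InvalidInputError):
            TreatmentProfile("X", 1.5, 0.1, 0.5, 0.3)


class TestScene:
    def test_reflectance_one_gives_white_reference(self, small_scene_spec):
        """Unit reflectance everywhere inverts to the white reference."""
        p = TreatmentProfile("X", 1.0, 1.0, 1.0, 0.0).quiet()
        spec = SceneSpec(
            height=16, width=16, background_reflectance=1.0,
            vnir_wavelengths=small_scene_spec.vnir_wavelengths,
            swir_wavelengths=small_scene_spec.swir_wavelengths,
        )
        sc = generate_scene(spec, p, rng=np.random.default_rng(0))
        np.testing.assert_allclose(
            sc.vnir.raw.data, np.broadcast_to(sc.vnir.refs.white, sc.vnir.raw.shape)
        )

    def test_reflectance_zero_gives_dark_reference(self, small_scene_spec):
        p = TreatmentProfile("X", 0.0, 0.0, 0.0, 0.0).quiet()
        spec = SceneSpec(
            height=16, width=16, background_reflectance=0.0,
            vnir_wavelengths=small_scene_spec.vnir_wavelengths,
            swir_wavelengths=small_scene_spec.swir_wavelengths,
        )
        sc = generate_scene(spec, p, rng=np.random.default_rng(0))
        np.testing.assert_allclose(
            sc.vnir.raw.data, np.broadcast_to(sc.vnir.refs.dark, sc.vnir.raw.shape)
        )

    def test_calibration_round_trip_noiseless(self, quiet_scene, quiet_profiles):
        """calibrate(generate_scene(...)) recovers the profile curve exactly."""
        for cap in (quiet_scene.vnir, quiet_scene.swir):
            cal = calibrate(cap.raw, cap.refs)
            expected = base_curve(quiet_profiles["LNHP"], cap.wavelengths)
            err = np.abs(cal.data[quiet_scene.mask] - expected).max()
            assert err < 1e-10

    def test_white_below_dark_rejected(self, small_scene_spec, profiles):
        with pytest.raises(InvalidInputError):
            generate_scene(
                small_scene_spec, profiles["HNHP"], white_level=50.0,
                dark_level=100.0, rng=np.random.default_rng(0),
            )

    def test_calibrated_reflectance_in_unit_interval(self, noisy_scene):
        cal = calibrate(noisy_scene.vnir.raw, noisy_scene.vnir.refs)
        sd = default_profiles()["HNHP"].noise_sd
        assert cal.data.min() >= -4 * sd and cal.data.max() <= 1 + 4 * sd


class TestDataset:
    def test_balanced_counts(self, coarse_scene_spec):
        scenes = generate_dataset(1, coarse_scene_spec, seed=0)
        assert len(scenes) == 4
        scenes = generate_dataset(3, coarse_scene_spec, seed=0)
        labels = [s.label for s in scenes]
        assert len(scenes) == 12
        assert all(labels.count(t) == 3 for t in ("HNHP", "HNLP", "LNHP", "LNLP"))

    def test_deterministic_under_seed(self, coarse_scene_spec):
        a = generate_dataset(2, coarse_scene_spec, seed=5)
        b = generate_dataset(2, coarse_scene_spec, seed=5)
        assert [s.label for s in a] == [s.label for s in b]
        np.testing.assert_array_equal(a[3].vnir.raw.data, b[3].vnir.raw.data)
        np.testing.assert_array_equal(a[3].mask, b[3].mask)

    def test_rejects_nonpositive_count(self, coarse_scene_spec):
        with pytest.raises(InvalidInputError):
            generate_dataset(0, coarse_scene_spec)

    def test_class_separability(self, tiny_dataset):
        """Between-class spread of class-mean spectra exceeds within-class."""
        means, withins = {}, []
        for label in ("HNHP", "HNLP", "LNHP", "LNLP"):
            pix = []
            for s in tiny_dataset:
                if s.label != label:
                    continue
                cal = calibrate(s.vnir.raw, s.vnir.refs)
                pix.append(cal.data[s.mask])
            pix = np.concatenate(pix)
            mu = pix.mean(axis=0)
            means[label] = mu
            withins.append(np.linalg.norm(pix - mu, axis=1).mean())
        labels = list(means)
        between = np.mean(
            [
                np.linalg.norm(means[a] - means[b])
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            ]
        )
        assert between > np.mean(withins)

    def test_scene_io_round_trip(self, tiny_dataset, tmp_path):
        """write_scene persists ENVI rasters readable back bit-exactly."""
        from hsin.hsi_io import read_envi
        from hsin.synth import write_scene

        scene = tiny_dataset[0]
        write_scene(scene, str(tmp_path))
        back = read_envi(str(tmp_path / f"{scene.scene_id}_vnir"))
        np.testing.assert_allclose(back.data, scene.vnir.raw.data, rtol=1e-6)
        assert (tmp_path / "manifest.csv").exists()
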