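"""Phantom construction and the single-LED capture forward model."""

import numpy as np
import pytest

from ledhsi.instrument import CameraModel, LEDChannel
from ledhsi.simulate import (
    ReflectanceSpectrum,
    acquire_dark,
    acquire_hypercube,
    acquire_white,
    band_gain,
    capture_frame,
    make_contrast_pair,
    make_phantom,
    make_tissue_spectrum,
)


class TestSpectra:
    def test_flat_baseline(self):
        s = make_tissue_spectrum(baseline=0.5)
        assert np.all(s(np.arange(400, 900, 50)) == 0.5)

    def test_bump_adds_at_center(self):
        s = make_tissue_spectrum(baseline=0.2, bumps=[(660, 30, 0.4)])
        assert s([660.0])[0] == pytest.approx(0.6)

    def test_values_clipped_to_unit_interval(self):
        s = ReflectanceSpectrum(baseline=0.9, bumps=((600, 50, 0.5), (800, 50, -1.5)))
        vals = s(np.arange(380, 1001))
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_contrast_pair_differs_only_at_configured_bands(self):
        a, b = make_contrast_pair(delta=0.15, bands=(505, 660))
        wl = np.array([405, 450, 505, 555, 610, 660, 770, 910], float)
        diff = b(wl) - a(wl)
        assert diff[wl == 505][0] == pytest.approx(0.15)
        assert diff[wl == 660][0] == pytest.approx(0.15)
        others = diff[(wl != 505) & (wl != 660)]
        assert np.all(np.abs(others) < 1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_tissue_spectrum(baseline=1.5)
        with pytest.raises(ValueError):
            ReflectanceSpectrum(baseline=0.5, bumps=((600, 5, 0.1),))
        with pytest.raises(KeyError):
            make_tissue_spectrum("no-such-tissue")

    def test_seeded_spectrum_reproducible(self):
        s1 = make_tissue_spectrum(seed=11)
        s2 = make_tissue_spectrum(seed=11)
        wl = np.arange(400, 950, 10)
        assert np.array_equal(s1(wl), s2(wl))


class TestPhantom:
    def test_label_count_and_determinism(self):
        p1 = make_phantom(64, 64, n_tissues=2, glare_spots=2, seed=5)
        p2 = make_phantom(64, 64, n_tissues=2, glare_spots=2, seed=5)
        assert np.array_equal(p1.label_map, p2.label_map)
        assert np.array_equal(p1.glare_mask, p2.glare_mask)
        assert set(np.unique(p1.label_map)) == {0, 1, 2}

    def test_requires_at_least_one_tissue(self):
        with pytest.raises(ValueError):
            make_phantom(64, 64, n_tissues=0, seed=0)

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError):
            make_phantom(24, 24, n_tissues=30, seed=0)

    def test_ground_truth_tracks_spectra(self, led_array, camera):
        p = make_phantom(64, 64, n_tissues=2, seed=1, led_array=led_array,
                         camera=camera)
        for lbl, spec in p.spectra.items():
            # band-effective reflectance tracks the point sample; the widest
            # LED lines average over spectral features, so agreement is loose
            point = spec(p.band_wavelengths)
            assert np.allclose(p.ground_truth[lbl], point, atol=0.05)


class TestCaptureFrame:
    def test_dark_frame_is_constant_dark_mean(self, camera, geometry):
        frame = capture_frame(None, None, camera, geometry, noise_on=False,
                              shape=(32, 32))
        assert np.all(frame == round(camera.dark_mean))

    def test_zero_reflectance_equals_dark(self, camera, geometry):
        ch = LEDChannel(500, 20, 60)
        lit = capture_frame(0.0, ch, camera, geometry, noise_on=False, shape=(32, 32))
        dark = capture_frame(None, None, camera, geometry, noise_on=False,
                             shape=(32, 32))
        assert np.array_equal(lit, dark)

    def test_linearity_in_reflectance(self, geometry):
        # flat wide illumination, no noise: dark-subtracted counts double
        cam = CameraModel(rows=16, cols=16, dark_mean=0.0)
        ch = LEDChannel(550, 20, 178)  # nearly flat field over the scene
        lo = capture_frame(0.25, ch, cam, geometry, noise_on=False, shape=(16, 16))
        hi = capture_frame(0.5, ch, cam, geometry, noise_on=False, shape=(16, 16))
        ratio = hi.astype(float) / lo.astype(float)
        assert np.allclose(ratio, 2.0, atol=0.02)

    def test_negative_exposure_rejected(self, camera, geometry):
        with pytest.raises(ValueError):
            capture_frame(0.5, LEDChannel(500, 20, 60), camera, geometry,
                          exposure=-1.0)

    def test_glare_forced_to_full_scale_every_band(self, led_array, camera,
                                                   geometry):
        p = make_phantom(64, 64, n_tissues=1, glare_spots=3, seed=2,
                         led_array=led_array, camera=camera)
        cube = acquire_hypercube(p, led_array, camera, geometry, noise_on=False,
                                 seed=0)
        assert np.all(cube.data[p.glare_mask, :] == camera.full_scale)


class TestAcquisition:
    def test_cube_bands_follow_array_order(self, noiseless_session, led_array):
        raw = noiseless_session["raw"]
        assert raw.data.shape == (64, 64, 18)
        assert np.array_equal(raw.band_wavelengths, led_array.wavelengths)

    def test_timestamps_span_one_cube_period(self, noiseless_session):
        # 18 channels x (1 + 1) frames at 120 fps -> 0.30 s per hypercube
        meta = noiseless_session["raw"].metadata
        assert meta["cube_duration_s"] == pytest.approx(0.30)
        starts = np.asarray(meta["band_start_s"])
        assert starts[0] == 0.0
        assert np.allclose(np.diff(starts), 2 / 120)

    def test_noiseless_capture_ignores_seed(self, led_array, camera, geometry):
        p = make_phantom(64, 64, n_tissues=1, seed=4, led_array=led_array,
                         camera=camera)
        c1 = acquire_hypercube(p, led_array, camera, geometry, noise_on=False,
                               seed=1)
        c2 = acquire_hypercube(p, led_array, camera, geometry, noise_on=False,
                               seed=99)
        assert np.array_equal(c1.data, c2.data)

    def test_white_stack_above_dark_everywhere(self, noiseless_session, camera):
        den = noiseless_session["denominator"]
        frac = (den > 0).mean(axis=(0, 1))
        assert frac.min() >= 0.99

    def test_white_peak_ordering_follows_power_times_qe(
        self, led_array, camera, geometry
    ):
        # at each LED's own footprint center the illumination equals its
        # relative power, so peak counts order as relative_power x response
        from ledhsi.simulate import target_plane_coords

        white = acquire_white(
            led_array, camera, geometry, shape=(64, 64), noise_on=False, seed=0
        )
        xg, yg = target_plane_coords((64, 64), geometry)
        peaks = []
        for b, ch in enumerate(led_array.channels):
            i = np.unravel_index(
                np.argmin((xg - ch.position[0]) ** 2 + (yg - ch.position[1]) ** 2),
                xg.shape,
            )
            peaks.append(white.data[i[0], i[1], b] - camera.dark_mean)
        predicted = np.array(
            [ch.relative_power * band_gain(ch, camera) for ch in led_array.channels]
        )
        assert np.array_equal(np.argsort(np.array(peaks)), np.argsort(predicted))

    def test_shot_noise_snr_matches_poisson_limit(self, geometry):
        # shot noise only: SNR_dB of a flat field with mean N -> 10 log10 N
        from ledhsi.spectral import snr_db

        cam = CameraModel(rows=100, cols=100, bit_depth=16, dark_mean=0.0,
                          dark_sigma=0.0, read_sigma=0.0, full_well_scale=5000.0)
        ch = LEDChannel(560, 20, 178)
        frame = capture_frame(1.0, ch, cam, geometry, noise_on=True,
                              rng=np.random.default_rng(0), shape=(100, 100))
        vals = frame.astype(float)
        n = vals.mean()
        assert n > 100
        assert snr_db(vals) == pytest.approx(10 * np.log10(n), abs=0.5)

    def test_dark_acquisition_shapes(self, camera):
        d = acquire_dark(camera, shape=(64, 64), noise_on=False, seed=0)
        assert d.data.shape == (64, 64)
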