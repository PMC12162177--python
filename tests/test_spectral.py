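"""Signature extraction, normalization, SNR, and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ledhsi.calibration import CalibratedCube
from ledhsi.spatial import ROIMask
from ledhsi.spectral import (
    SpectralSignature,
    compare_groups,
    extract_signature,
    normalize_signature,
    snr_db,
)

WL = np.array([450.0, 550.0, 650.0, 750.0])


def _sig(values, wl=None):
    values = np.asarray(values, dtype=float)
    wl = WL if wl is None else wl
    return SpectralSignature(band_wavelengths=wl[: len(values)], mean=values,
                             std=np.zeros_like(values),
                             n_pixels=np.full(len(values), 50))


def _const_cube(value, shape=(10, 10, 4)):
    data = np.full(shape, value, dtype=float)
    return CalibratedCube(data=data, validity_mask=np.ones(shape, dtype=bool),
                          band_wavelengths=WL[: shape[2]])


class TestExtract:
    def test_constant_cube(self):
        roi = ROIMask(np.ones((10, 10), dtype=bool))
        sig = extract_signature(_const_cube(0.5), roi)
        assert np.all(sig.mean == 0.5)
        assert np.all(sig.std == 0.0)
        assert np.all(sig.n_pixels == 100)

    def test_single_pixel_roi(self):
        cube = _const_cube(0.5)
        cube.data[3, 4, :] = 0.77
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 4] = True
        sig = extract_signature(cube, ROIMask(mask))
        assert np.all(sig.mean == 0.77)
        assert np.all(sig.std == 0.0)
        assert np.all(sig.n_pixels == 1)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_signature(_const_cube(0.5), ROIMask(np.zeros((10, 10), bool),
                                                        provenance={"empty": True}))

    def test_only_valid_pixels_contribute(self):
        cube = _const_cube(0.5)
        cube.data[:5, :, 0] = 9.9
        cube.validity_mask[:5, :, 0] = False
        sig = extract_signature(cube, ROIMask(np.ones((10, 10), bool)))
        assert sig.mean[0] == 0.5
        assert sig.n_pixels[0] == 50

    def test_phantom_signature_matches_ground_truth(self, noiseless_session):
        """End-to-end: the extracted tissue signature equals the phantom's
        known reflectance / 0.99, within quantization."""
        phantom = noiseless_session["phantom"]
        cal = noiseless_session["cal"]
        den = noiseless_session["denominator"]
        for lbl in (1, 2):
            roi = ROIMask((phantom.label_map == lbl) & ~phantom.glare_mask)
            sig = extract_signature(cal, roi)
            step = np.array([
                (1.0 / den[:, :, b][roi.mask & cal.validity_mask[:, :, b]]).max()
                for b in range(cal.n_bands)
            ])
            assert np.all(np.abs(sig.mean - phantom.ground_truth[lbl] / 0.99) <= step)


class TestNormalize:
    def test_affine_map_to_unit_interval(self):
        out = normalize_signature(_sig([2.0, 4.0, 6.0]))
        assert np.allclose(out.normalized, [0.0, 0.5, 1.0])

    def test_flat_signature_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            normalize_signature(_sig([0.5, 0.5, 0.5]))

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), a=st.floats(0.1, 10.0),
           b=st.floats(-5.0, 5.0))
    def test_affine_invariance_and_idempotence(self, seed, a, b):
        vals = np.random.default_rng(seed).random(4)
        if np.ptp(vals) < 1e-9:
            return
        base = normalize_signature(_sig(vals)).normalized
        scaled = normalize_signature(_sig(a * vals + b)).normalized
        assert np.allclose(base, scaled, atol=1e-9)
        again = normalize_signature(_sig(base)).normalized
        assert np.allclose(again, base, atol=1e-12)
        assert base.min() == 0.0 and base.max() == 1.0


class TestSNR:
    def test_closed_form_points(self):
        vals = np.array([9.0, 10.0, 11.0])  # mean 10, std sqrt(2/3)
        mu, sd = vals.mean(), vals.std()
        assert snr_db(vals) == pytest.approx(20 * np.log10(mu / sd))
        # mu/sigma = 10 -> 20 dB
        rng = np.random.default_rng(0)
        x = rng.normal(100.0, 10.0, 200_000)
        assert snr_db(x) == pytest.approx(20.0, abs=0.1)

    def test_poisson_flat_field(self):
        vals = np.random.default_rng(1).poisson(1000, (100, 100))
        assert snr_db(vals) == pytest.approx(30.0, abs=0.5)

    def test_scale_invariance(self):
        vals = np.random.default_rng(2).poisson(500, 5000).astype(float)
        assert snr_db(vals * 37.5) == pytest.approx(snr_db(vals))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            snr_db(np.full(10, 5.0))
        with pytest.raises(ValueError):
            snr_db(np.array([-3.0, 1.0, -4.0, 2.0]))


class TestCompareGroups:
    def test_identical_groups_no_flags(self):
        sigs = [_sig([0.1, 0.5, 0.3, 0.9]) for _ in range(4)]
        res = compare_groups(sigs, sigs, direction="greater")
        assert np.all(res.t_statistic == 0.0)
        assert np.all(res.p_value == 0.5)
        assert not res.significant.any()

    def test_matches_textbook_pooled_t(self):
        """n=3 vs 3 hand case: pooled t and one-tailed p frozen from an
        explicit-formula + numerical-integration oracle."""
        a = [_sig([v, v]) for v in (0.10, 0.20, 0.15)]
        b = [_sig([v, v]) for v in (0.05, 0.12, 0.08)]
        res = compare_groups(a, b, direction="greater", use_normalized=False)
        assert res.t_statistic[0] == pytest.approx(1.8898223650, abs=1e-9)
        assert res.p_value[0] == pytest.approx(0.0658883, abs=1e-4)

    def test_planted_effect_recovered_at_exactly_those_bands(self):
        rng = np.random.default_rng(5)
        base = np.array([0.2, 0.5, 0.4, 0.8])
        effect = np.array([0.0, 0.3, 0.0, 0.0])  # strong planted shift, band 1
        a = [_sig(base + effect + rng.normal(0, 0.01, 4)) for _ in range(10)]
        b = [_sig(base + rng.normal(0, 0.01, 4)) for _ in range(10)]
        res = compare_groups(a, b, direction="greater", use_normalized=False)
        assert res.significant[1]
        assert not res.significant[[0, 2, 3]].any()

    def test_power_monotone_in_effect_and_n(self):
        wl18 = np.linspace(405, 910, 18)
        base = 0.5 + 0.2 * np.sin(np.linspace(0, 3, 18))
        sigma = 0.05

        def power(delta, n, reps=150, seed=9):
            rng = np.random.default_rng(seed)
            eff = np.zeros(18)
            eff[5] = delta
            hits = 0
            for _ in range(reps):
                a = [_sig(base + eff + rng.normal(0, sigma, 18), wl18)
                     for _ in range(n)]
                b = [_sig(base + rng.normal(0, sigma, 18), wl18) for _ in range(n)]
                hits += compare_groups(a, b, direction="greater").significant[5]
            return hits / reps

        p_small = power(1 * sigma, 6)
        p_big = power(3 * sigma, 6)
        p_big_n = power(3 * sigma, 14)
        assert p_small <= p_big + 0.05
        assert p_big <= p_big_n + 0.05
        assert p_big_n > p_small

    def test_direction_must_be_declared(self):
        sigs = [_sig([0.1, 0.2, 0.3, 0.4]) for _ in range(3)]
        with pytest.raises(ValueError):
            compare_groups(sigs, sigs, direction=None)
        with pytest.raises(ValueError):
            compare_groups(sigs[:1], sigs, direction="greater")

    def test_auto_direction_warns(self):
        rng = np.random.default_rng(6)
        a = [_sig(rng.random(4) + 0.2) for _ in range(4)]
        b = [_sig(rng.random(4)) for _ in range(4)]
        with pytest.warns(UserWarning, match="type-I"):
            compare_groups(a, b, direction="auto", use_normalized=False)

    def test_bonferroni_is_more_conservative(self):
        rng = np.random.default_rng(7)
        base = np.linspace(0.2, 0.8, 4)
        a = [_sig(base + 0.05 + rng.normal(0, 0.03, 4)) for _ in range(8)]
        b = [_sig(base + rng.normal(0, 0.03, 4)) for _ in range(8)]
        plain = compare_groups(a, b, direction="greater", use_normalized=False)
        bonf = compare_groups(a, b, direction="greater", use_normalized=False,
                              correction="bonferroni")
        assert np.all(bonf.p_value >= plain.p_value)
        assert bonf.significant.sum() <= plain.significant.sum()
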