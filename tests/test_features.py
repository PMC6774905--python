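"""Predictor variables: depolarization ratio, wingbeat frequency, log-ratios."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import entolidar as el
from entolidar.features import (
    DELTA_BODY_FEATURE,
    FEATURE_NAMES,
    LOG_RATIO_PAIRS,
    FeatureExtractionError,
    WbfResult,
    build_feature_vector,
    comb_score,
)
from entolidar.simulate import SIGMA_COMPONENTS

from conftest import featurize, frozen


class TestDepolarizationRatio:
    @pytest.mark.parametrize(
        "i_perp,i_par,g,expected",
        [
            (0.45, 1.0, 1.0, 0.45),  # non-gravid body mean
            (0.0, 1.0, 1.0, 0.0),
            (1.0, 4.0, 2.0, 0.5),
        ],
    )
    def test_values(self, i_perp, i_par, g, expected):
        assert el.depolarization_ratio(i_perp, i_par, g) == pytest.approx(expected)

    def test_zero_copolarized_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            el.depolarization_ratio(1.0, 0.0)

    def test_negative_input_is_error(self):
        with pytest.raises(ValueError):
            el.depolarization_ratio(-1.0, 1.0)

    def test_intensity_and_cross_section_forms_agree(self, quiet_beam, nongravid_spec):
        """delta from raw intensities with G equals the calibrated sigma ratio."""
        ev = el.simulate_event(frozen(nongravid_spec), quiet_beam, seed=3)
        dec = el.separate_body_wing(ev)
        g = 1.7
        calib = el.CalibrationModel(g_factor=g)
        sigma = el.extract_cross_sections(dec, calib)
        i_perp = dec.body_i1320perp.max()
        i_par = dec.body_i1320par.max()
        from_intensities = el.depolarization_ratio(i_perp, i_par, g)
        from_sigma = sigma["1320perp_b"] / sigma["1320par_b"]
        assert from_intensities == pytest.approx(from_sigma, rel=1e-9)


class TestWbfEstimation:
    def test_pure_sine_recovered_with_no_harmonics(self):
        fs = 30517.0
        t = np.arange(4096) / fs
        r = el.estimate_wbf(np.sin(2 * np.pi * 400.0 * t), fs)
        assert r.detected
        assert r.wbf_hz == pytest.approx(400.0, abs=fs / 1024)
        assert r.h1_power_ratio < 0.01

    def test_simulated_348_hz_recovered(self, quiet_beam, nongravid_spec):
        spec = frozen(nongravid_spec, wbf_mean=348.0)
        ev = el.simulate_event(spec, quiet_beam, seed=5)
        dec = el.separate_body_wing(ev)
        r = el.estimate_wbf(dec.wing_i924, ev.sampling_rate_hz)
        assert r.detected
        assert r.wbf_hz == pytest.approx(348.0, abs=2.0)
        assert r.h1_power_ratio > 0.01  # harmonics present for the rectified comb

    def test_strong_second_harmonic_does_not_cause_octave_error(self):
        """A 300 Hz comb with dominant 600 Hz content must read 300 Hz, and the
        estimator must agree with a brute-force evaluation of the comb score."""
        fs = 30517.0
        t = np.arange(4096) / fs
        x = np.clip(
            0.3 * np.cos(2 * np.pi * 300.0 * t) + 1.0 * np.cos(2 * np.pi * 600.0 * t),
            0.0,
            None,
        )
        r = el.estimate_wbf(x, fs)
        assert r.wbf_hz == pytest.approx(300.0, abs=3.0)
        # independent brute force over a dense grid using a plain FFT spectrum
        spectrum = np.abs(np.fft.rfft(x * np.hanning(len(x)), n=4 * len(x))) ** 2
        freqs = np.fft.rfftfreq(4 * len(x), 1.0 / fs)
        grid = np.linspace(150.0, 900.0, 3001)
        scores = comb_score(freqs, spectrum, grid)
        assert grid[np.argmax(scores)] == pytest.approx(300.0, abs=3.0)

    def test_series_too_short_for_range_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            el.estimate_wbf(np.ones(64), 30517.0, f_range=(150.0, 900.0))

    def test_noise_only_series_not_detected(self):
        rng = np.random.default_rng(0)
        r = el.estimate_wbf(rng.standard_normal(4096) * 0.01, 30517.0)
        assert not r.detected


class TestFeatureVector:
    def _wbf(self, f=350.0):
        return WbfResult(detected=True, wbf_hz=f, h1_power_ratio=0.2, h2_power_ratio=0.05)

    def test_equal_cross_sections_give_zero_log_ratios(self):
        sigma = {c: 2.0 for c in SIGMA_COMPONENTS}
        fv = build_feature_vector(sigma, self._wbf())
        np.testing.assert_allclose(fv.values[:15], 0.0, atol=1e-12)
        assert fv["wbf_hz"] == 350.0

    def test_body_depolarization_pair_is_log_of_0_62(self):
        sigma = {c: 1.0 for c in SIGMA_COMPONENTS}
        sigma["1320perp_b"] = 0.62
        fv = build_feature_vector(sigma, self._wbf())
        assert fv[DELTA_BODY_FEATURE] == pytest.approx(np.log(0.62), abs=1e-9)
        assert fv[DELTA_BODY_FEATURE] == pytest.approx(-0.478, abs=1e-3)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_swapping_pair_order_negates_log_ratio(self, a, b):
        assert np.log(a / b) == pytest.approx(-np.log(b / a), rel=1e-9, abs=1e-12)

    def test_nonpositive_sigma_rejected_with_reason(self):
        sigma = {c: 1.0 for c in SIGMA_COMPONENTS}
        sigma["924_w"] = 0.0
        with pytest.raises(FeatureExtractionError, match="924_w"):
            build_feature_vector(sigma, self._wbf())

    def test_undetected_wbf_rejected(self):
        sigma = {c: 1.0 for c in SIGMA_COMPONENTS}
        with pytest.raises(FeatureExtractionError, match="wingbeat"):
            build_feature_vector(sigma, WbfResult(detected=False))

    def test_exactly_18_named_features(self):
        assert len(FEATURE_NAMES) == 18
        assert len(LOG_RATIO_PAIRS) == 15
        assert len(set(FEATURE_NAMES)) == 18


class TestScaleInvariance:
    def test_ratio_features_invariant_to_global_trace_scaling(self, gravid_spec, beam):
        """Position coefficient and laser power cancel in every log-ratio."""
        ev = el.simulate_event(gravid_spec, el.BeamModel(noise_sd=0.0), seed=31)
        k = 3.7
        scaled = el.RawEvent(
            i924=k * ev.i924,
            i1320par=k * ev.i1320par,
            i1320perp=k * ev.i1320perp,
            sampling_rate_hz=ev.sampling_rate_hz,
            label=ev.label,
        )
        fvs = []
        for e in (ev, scaled):
            dec = el.separate_body_wing(e)
            sigma = el.extract_cross_sections(dec)
            wbf = el.estimate_wbf(dec.wing_i924, e.sampling_rate_hz)
            fvs.append(build_feature_vector(sigma, wbf))
        np.testing.assert_allclose(fvs[0].values[:15], fvs[1].values[:15], atol=1e-9)
        assert fvs[0]["wbf_hz"] == pytest.approx(fvs[1]["wbf_hz"], abs=1e-6)


class TestAssembleDataset:
    def test_counts_column_order_and_determinism(self, beam):
        events = el.simulate_dataset(el.two_class_specs(), 8, beam, seed=77)
        ds1, drops1 = featurize(events)
        ds2, drops2 = featurize(events)
        assert len(ds1) + len(drops1) == 16
        assert ds1.feature_names == FEATURE_NAMES
        np.testing.assert_array_equal(ds1.X, ds2.X)

    def test_dropped_events_are_logged(self, beam):
        events = el.simulate_dataset(el.two_class_specs(), 4, beam, seed=78)
        pairs = []
        for ev in events:
            dec = el.separate_body_wing(ev)
            el.extract_cross_sections(dec)
            pairs.append((dec, ev.label))
        # sabotage one event's wing cross section
        pairs[0][0].sigma["924_w"] = 0.0
        with pytest.warns(UserWarning, match="dropped 1"):
            ds, drops = el.assemble_dataset(pairs)
        assert len(ds) == 7
        assert drops[0]["index"] == 0 and "924_w" in drops[0]["reason"]

    def test_class_losing_all_events_is_error(self, beam):
        events = el.simulate_dataset(el.two_class_specs(), 2, beam, seed=79)
        pairs = []
        for ev in events:
            dec = el.separate_body_wing(ev)
            el.extract_cross_sections(dec)
            if ev.label == "culex_female_gravid":
                dec.sigma["924_w"] = 0.0
            pairs.append((dec, ev.label))
        with pytest.raises(ValueError, match="culex_female_gravid"):
            el.assemble_dataset(pairs)

    def test_class_means_recovered_from_moderate_sample(self, beam):
        """Extracted delta_b and WBF means land near the generating class means."""
        events = el.simulate_dataset(el.two_class_specs(), 120, beam, seed=2024)
        ds, _ = featurize(events)
        for label, d_true, f_true in (
            ("culex_female_nongravid", 0.45, 347.0),
            ("culex_female_gravid", 0.62, 365.0),
        ):
            mask = ds.y == label
            delta = np.exp(ds.column(DELTA_BODY_FEATURE)[mask])
            wbf = ds.column("wbf_hz")[mask]
            n = mask.sum()
            assert abs(delta.mean() - d_true) < 3.5 * delta.std(ddof=1) / np.sqrt(n)
            assert abs(wbf.mean() - f_true) < 3.5 * wbf.std(ddof=1) / np.sqrt(n)
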