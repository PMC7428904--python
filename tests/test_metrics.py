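"""Time-domain and spectral HRV metric computation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ushrv import (
    PreprocessConfig,
    RRSeries,
    SubjectModel,
    compute_metrics,
    generate_rr,
    pnn50,
    rmssd,
    sdnn,
    spectral_analysis,
)
from ushrv.metrics import (
    band_powers,
    interpolate_tachogram,
    normalized_powers,
    psd,
)
from ushrv.preprocess import correct_artefacts, detect_artefacts, detrend_smoothness_priors
from ushrv.synthetic import band_power_truth


class TestTimeDomain:
    def test_sdnn_hand_value(self):
        assert sdnn(RRSeries([800.0, 820.0, 840.0])) == pytest.approx(20.0, abs=1e-9)

    def test_rmssd_hand_value(self):
        expect = math.sqrt((100 + 400 + 225) / 3)
        assert rmssd(RRSeries([800.0, 810.0, 790.0, 805.0])) == pytest.approx(expect, abs=1e-9)

    def test_rmssd_alternating(self):
        z = np.where(np.arange(100) % 2, 810.0, 800.0)
        assert rmssd(RRSeries(z)) == pytest.approx(10.0, abs=1e-12)

    def test_pnn50_hand_count(self):
        assert pnn50(RRSeries([800.0, 860.0, 820.0, 880.0])) == pytest.approx(200 / 3)

    def test_pnn50_boundary_is_strict(self):
        assert pnn50(RRSeries([800.0, 850.0, 800.0])) == 0.0

    @pytest.mark.parametrize("fn", [sdnn, rmssd, pnn50])
    def test_constant_series_is_zero(self, fn, constant_series):
        assert fn(constant_series) == 0.0

    @pytest.mark.parametrize("fn", [sdnn, rmssd, pnn50])
    def test_too_short_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(RRSeries([800.0]))

    def test_sdnn_matches_two_pass_oracle(self, rng):
        z = rng.uniform(600, 1100, 500)
        mean = sum(z) / len(z)
        var = sum((v - mean) ** 2 for v in z) / (len(z) - 1)
        assert sdnn(RRSeries(z)) == pytest.approx(math.sqrt(var), rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=5.0))
    def test_scale_equivariance(self, c):
        base = np.array([800.0, 830.0, 790.0, 815.0, 805.0])
        scaled = RRSeries(800.0 + c * (base - 800.0))
        assert sdnn(scaled) == pytest.approx(c * sdnn(RRSeries(base)), rel=1e-9)
        assert rmssd(scaled) == pytest.approx(c * rmssd(RRSeries(base)), rel=1e-9)


class TestTachogram:
    def test_constant_series_all_zero_after_mean_removal(self):
        rr = RRSeries(np.full(100, 1000.0))
        _, sig = interpolate_tachogram(rr)
        np.testing.assert_allclose(sig, 0.0, atol=1e-9)

    def test_grid_spacing_quarter_second(self):
        rr = RRSeries(np.full(100, 1000.0))
        t, _ = interpolate_tachogram(rr, fs=4.0)
        np.testing.assert_allclose(np.diff(t), 0.25)

    def test_sinusoid_reconstructed(self):
        rr = generate_rr(SubjectModel(a_vlf=0, a_hf=0, a_lf=30, sigma_wn=0, seed=0), 300)
        t, sig = interpolate_tachogram(rr)
        truth = 30 * np.sin(2 * np.pi * 0.1 * t)
        r = np.corrcoef(sig, truth)[0, 1]
        assert r > 0.99


class TestSpectrum:
    def test_pure_tone_power_parseval(self):
        t = np.arange(0, 300, 0.25)
        sig = 40.0 * np.sin(2 * np.pi * 0.25 * t)
        f, p = psd(sig, 4.0)
        total = np.trapezoid(p, f)
        assert total == pytest.approx(40.0**2 / 2, rel=0.05)

    def test_white_noise_power_parseval(self, rng):
        sig = rng.normal(0, 5.0, 4096)
        f, p = psd(sig, 4.0)
        assert np.trapezoid(p, f) == pytest.approx(np.var(sig), rel=0.10)

    def test_zero_signal_zero_psd(self):
        f, p = psd(np.zeros(512), 4.0)
        assert np.all(p == 0)

    @pytest.mark.parametrize(
        "freq, band_idx", [(0.1, 1), (0.25, 2)], ids=["lf_tone", "hf_tone"]
    )
    def test_tone_lands_in_its_band(self, freq, band_idx):
        t = np.arange(0, 300, 0.25)
        sig = 30.0 * np.sin(2 * np.pi * freq * t)
        f, p = psd(sig, 4.0)
        powers = band_powers(f, p)
        assert powers[band_idx] / sum(powers) >= 0.95

    def test_flat_psd_splits_by_band_width(self):
        f = np.linspace(0, 2, 2001)
        p = np.full_like(f, 10.0)
        vlf, lf, hf = band_powers(f, p)
        total = vlf + lf + hf
        np.testing.assert_allclose(
            [vlf / total, lf / total, hf / total],
            np.array([0.04, 0.11, 0.25]) / 0.4,
            atol=1e-6,
        )

    def test_grid_must_reach_top_band_edge(self):
        f = np.linspace(0, 0.3, 100)
        with pytest.raises(ValueError, match="below"):
            band_powers(f, np.ones_like(f))

    @pytest.mark.parametrize(
        "triple, expected",
        [((10, 30, 60), (10, 30, 60)), ((0, 0, 5), (0, 0, 100))],
    )
    def test_normalized_powers_examples(self, triple, expected):
        np.testing.assert_allclose(normalized_powers(*triple), expected)

    def test_zero_total_power_flagged_missing(self):
        out = normalized_powers(0.0, 0.0, 0.0)
        assert all(math.isnan(v) for v in out)

    @given(
        st.tuples(
            st.floats(min_value=1e-6, max_value=1e6),
            st.floats(min_value=1e-6, max_value=1e6),
            st.floats(min_value=1e-6, max_value=1e6),
        )
    )
    def test_normalized_powers_sum_to_100(self, triple):
        assert sum(normalized_powers(*triple)) == pytest.approx(100.0, abs=1e-9)


class TestComputeMetrics:
    def test_composition_matches_manual_pipeline(self):
        rr = generate_rr(SubjectModel(seed=3), 300)
        cfg = PreprocessConfig()
        m = compute_metrics(rr, cfg)
        manual = correct_artefacts(rr, detect_artefacts(rr, cfg))
        manual = detrend_smoothness_priors(manual, cfg.detrend_lambda)
        assert m.sdnn == pytest.approx(sdnn(manual), rel=1e-12)
        assert m.rmssd == pytest.approx(rmssd(manual), rel=1e-12)
        spec = spectral_analysis(manual)
        assert m.nhf == pytest.approx(spec.nhf, rel=1e-12)

    def test_constant_series_spectral_flagged(self, constant_series):
        m = compute_metrics(constant_series)
        assert m.sdnn == m.rmssd == m.pnn50 == 0.0
        assert math.isnan(m.nvlf) and "spectral_undefined" in m.quality

    def test_deterministic(self):
        rr = generate_rr(SubjectModel(seed=11), 300)
        a, b = compute_metrics(rr), compute_metrics(rr)
        assert a == b

    def test_short_segment_flagged_low_confidence(self):
        rr = RRSeries(800.0 + 30 * np.sin(np.arange(20)))
        m = compute_metrics(rr)
        assert "low_confidence" in m.quality

    def test_nu_simplex_when_defined(self):
        rr = generate_rr(SubjectModel(seed=2), 300)
        m = compute_metrics(rr)
        assert m.nvlf + m.nlf + m.nhf == pytest.approx(100.0, abs=1e-6)


class TestParameterRecovery:
    def test_hf_twice_lf_amplitude_gives_power_ratio_near_four(self):
        model = SubjectModel(a_vlf=0.0, a_lf=15.0, a_hf=30.0, sigma_wn=0.0, seed=0)
        rr = generate_rr(model, 300)
        spec = spectral_analysis(rr)
        assert 3.2 <= spec.hf / spec.lf <= 4.8

    def test_band_truth_recovered_within_five_percent(self):
        model = SubjectModel(a_vlf=0.0, a_lf=0.0, a_hf=30.0, sigma_wn=0.0, seed=0)
        rr = generate_rr(model, 300)
        spec = spectral_analysis(rr)
        truth = band_power_truth(model)["hf"]
        assert spec.hf == pytest.approx(truth, rel=0.05)

    def test_vlf_estimate_degrades_with_shorter_windows(self):
        """One-minute nVLF strays further from the 5-minute value than 4-minute nVLF."""
        from ushrv.segmentation import default_scheme, extract

        segs = {s.label: s for s in default_scheme()}
        gap_1, gap_4 = [], []
        for seed in range(30):
            model = SubjectModel(seed=seed)
            rr = generate_rr(model, 300)
            cfg = PreprocessConfig(detrend_lambda=None, artefact_level="none")
            ref = compute_metrics(extract(rr, segs["0-5"]), cfg).nvlf
            one = compute_metrics(extract(rr, segs["0-1"]), cfg).nvlf
            four = compute_metrics(extract(rr, segs["0-4"]), cfg).nvlf
            gap_1.append(abs(one - ref))
            gap_4.append(abs(four - ref))
        assert np.mean(gap_1) > np.mean(gap_4)
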