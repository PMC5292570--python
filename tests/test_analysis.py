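import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myobench.analysis import (
    NoiseLevelThresholds,
    accuracy_summary,
    band_power_compare,
    classify_noise_level,
    harmonic_band_power,
    pearson_corr,
    rms_envelope,
    round_half_away,
    summarize,
)
from myobench.fixtures import load_table2
from myobench.semg_synth import (
    PPY_TRANSFER,
    WET_TRANSFER,
    MotionLabel,
    SourceModel,
    apply_electrode,
    synth_source,
)
from myobench.trace import MeasurementTrace

FS = 1600.0


class TestRmsEnvelope:
    def test_constant_input_gives_constant_envelope(self):
        trace = MeasurementTrace(np.full((2, 3200), 3.0), FS)
        env = rms_envelope(trace)
        assert np.allclose(env.samples, 3.0)

    def test_zero_input_gives_zero_envelope(self):
        env = rms_envelope(MeasurementTrace(np.zeros((1, 3200)), FS))
        assert np.all(env.samples == 0)

    def test_sinusoid_envelope_is_rms_amplitude(self):
        t = np.arange(3200) / FS
        tone = np.sin(2 * np.pi * 100 * t)[None, :]  # 100 ms window = 10 periods
        env = rms_envelope(MeasurementTrace(tone, FS), window_ms=100.0)
        assert np.allclose(env.samples, 1 / np.sqrt(2), atol=1e-6)

    def test_excluded_samples_are_skipped(self):
        x = np.full((1, 3200), 2.0)
        x[0, :160] = 100.0  # an excluded artifact burst
        trace = MeasurementTrace(x, FS)
        trace.excluded_mask[:160] = True
        env = rms_envelope(trace)
        # the first window is fully excluded (NaN); all others ignore the
        # masked burst and see only the clean 2 V signal
        assert np.isnan(env.samples[0, 0])
        assert np.allclose(env.samples[:, 1:], 2.0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            rms_envelope(MeasurementTrace(np.zeros((1, 100)), FS), window_ms=100.0)


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(500)
        assert pearson_corr(x, x).r == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, rng):
        x = rng.standard_normal(500)
        assert pearson_corr(x, -x).r == pytest.approx(-1.0)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_invariant_to_positive_affine_transforms(self, a, b):
        rng = np.random.default_rng(17)
        x, y = rng.standard_normal((2, 200))
        assert pearson_corr(a * x + b, y).r == pytest.approx(
            pearson_corr(x, y).r, rel=1e-9
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(10), np.arange(10.0))

    def test_two_electrode_views_of_one_source_correlate(self):
        model = SourceModel()
        source = synth_source(model, MotionLabel.FLEXION, 2.0, seed=31)
        import dataclasses

        wet = apply_electrode(
            source, dataclasses.replace(WET_TRANSFER, noise_density=2e-7), seed=1
        )
        ppy = apply_electrode(
            source, dataclasses.replace(PPY_TRANSFER, noise_density=2e-7), seed=2
        )
        r = pearson_corr(rms_envelope(wet), rms_envelope(ppy)).r
        assert r > 0.95


class TestSummarize:
    def test_constant_list_has_zero_sd(self):
        mean, sd = summarize([4.0, 4.0, 4.0])
        assert mean == 4.0 and sd == 0.0

    def test_matches_numpy_sample_statistics(self, rng):
        v = rng.standard_normal(50)
        mean, sd = summarize(v)
        assert mean == pytest.approx(np.mean(v))
        assert sd == pytest.approx(np.std(v, ddof=1))

    def test_single_value_has_undefined_sd(self):
        mean, sd = summarize([2.5])
        assert mean == 2.5 and np.isnan(sd)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestAccuracySummary:
    def test_all_perfect_table_means_100(self):
        rows = [
            {"task": t, "subject": s, "condition": c, "accuracy": 100.0}
            for t in ("relax", "close")
            for s in ("A", "B")
            for c in ("wet", "ppy")
        ]
        summ = accuracy_summary(pd.DataFrame(rows))
        assert (summ["overall"] == 100.0).all()
        assert (summ["per_task"] == 100.0).all().all()

    def test_row_order_does_not_matter(self):
        table = load_table2()
        shuffled = table.sample(frac=1.0, random_state=5)
        a = accuracy_summary(table)["overall"].sort_index()
        b = accuracy_summary(shuffled)["overall"].sort_index()
        assert list(a.index) == list(b.index)
        assert np.allclose(a.values, b.values)

    def test_missing_cells_rejected(self):
        table = load_table2().iloc[:-1]
        with pytest.raises(ValueError):
            accuracy_summary(table)


class TestNoiseLevel:
    def test_silent_trace_is_level_one(self):
        trace = MeasurementTrace(np.zeros((1, 1000)), FS)
        assert classify_noise_level(trace) == 1

    def test_rail_clipped_trace_is_level_three(self, rng):
        trace = MeasurementTrace(
            np.clip(20 * rng.standard_normal((1, 1000)), -9, 9), FS
        )
        assert classify_noise_level(trace) == 3

    def test_mid_band_trace_is_level_two(self):
        trace = MeasurementTrace(np.full((1, 1000), 3.0), FS)
        assert classify_noise_level(trace) == 2

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            NoiseLevelThresholds(v_lo=7.0)


class TestBandPower:
    def test_identical_traces_have_unit_ratios(self, rng):
        trace = MeasurementTrace(rng.standard_normal((3, 2048)), FS)
        rep = band_power_compare(trace, trace)
        assert rep["ratio_below"] == pytest.approx(1.0)
        assert rep["ratio_above"] == pytest.approx(1.0)

    def test_hf_boosted_view_raises_only_the_upper_band(self):
        source = synth_source(SourceModel(), MotionLabel.CLOSE, 2.0, seed=41)
        wet = apply_electrode(source, WET_TRANSFER)
        ppy = apply_electrode(source, PPY_TRANSFER)
        rep = band_power_compare(wet, ppy, split_hz=150.0)
        assert rep["ratio_above"] > rep["ratio_below"]

    def test_band_powers_match_direct_fft_sums(self, rng):
        x = rng.standard_normal((1, 1024))
        trace = MeasurementTrace(x, FS)
        rep = band_power_compare(trace, trace, split_hz=150.0)
        # independent oracle: rectangular-window periodogram from the DFT
        # (mean removed, matching the periodogram's constant detrend)
        spec = np.abs(np.fft.rfft(x[0] - x[0].mean())) ** 2
        freqs = np.fft.rfftfreq(1024, d=1 / FS)
        scale = np.full_like(spec, 2.0)
        scale[0] = scale[-1] = 1.0  # DC and Nyquist are not doubled
        psd = spec * scale / (FS * 1024)
        assert rep["a_below"] == pytest.approx(psd[freqs < 150].sum(), rel=1e-9)
        assert rep["a_above"] == pytest.approx(psd[freqs >= 150].sum(), rel=1e-9)

    def test_bad_split_rejected(self, rng):
        trace = MeasurementTrace(rng.standard_normal((1, 256)), FS)
        with pytest.raises(ValueError):
            band_power_compare(trace, trace, split_hz=900.0)


class TestHelpers:
    def test_harmonic_band_power_sees_an_injected_tone(self):
        t = np.arange(3200) / FS
        tone = MeasurementTrace(np.sin(2 * np.pi * 300 * t)[None, :], FS)
        silent = MeasurementTrace(1e-9 * np.ones((1, 3200)), FS)
        assert harmonic_band_power(tone) > 1e6 * harmonic_band_power(silent)

    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(83.35, 1, 83.4), (-83.35, 1, -83.4), (1046.9, 0, 1047.0), (0.8692, 2, 0.87)],
    )
    def test_round_half_away_from_zero(self, value, decimals, expected):
        assert round_half_away(value, decimals) == expected
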