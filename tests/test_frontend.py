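import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import periodogram

from myobench.frontend import (
    AmplifierSpec,
    FilterChainSpec,
    InterferenceModel,
    apply_meter_schedule,
    common_mode_coupling,
    exclude_saturated,
    imbalance_indices,
    simulate_measurement,
)
from myobench.semg_synth import (
    TABLE3_LEVEL_SPECS,
    ImpedanceState,
    MotionLabel,
    SourceModel,
    synth_source,
)
from myobench.trace import MeasurementTrace

FS = 1600.0


def balanced_state(mag=50_000.0, phase=-20.0):
    return ImpedanceState(mag, phase, mag, phase)


def mean_state(level):
    spec = TABLE3_LEVEL_SPECS[level]
    return ImpedanceState(
        spec.baseline_mag - spec.mag_diff_mean / 2,
        spec.baseline_phase + spec.phase_diff_mean / 2,
        spec.baseline_mag + spec.mag_diff_mean / 2,
        spec.baseline_phase - spec.phase_diff_mean / 2,
    )


def flat_trace(value=0.0, n=3200, n_ch=1):
    return MeasurementTrace(np.full((n_ch, n), value), FS)


class TestImbalanceIndices:
    def test_perfectly_balanced_pair_gives_zero(self):
        assert imbalance_indices(balanced_state()) == (0.0, 0.0)

    def test_printed_level1_pair(self):
        # 50 kOhm at -20 deg vs 51.3 kOhm at -19.4 deg realizes the printed
        # first level-1 row: 1300 Ohm and 0.6 deg
        state = ImpedanceState(50_000, -20.0, 51_300, -19.4)
        mag, phase = imbalance_indices(state)
        assert mag == pytest.approx(1300.0, abs=1e-6)
        assert phase == pytest.approx(0.6, abs=1e-9)

    @given(
        m1=st.floats(1e3, 2e5),
        m2=st.floats(1e3, 2e5),
        p1=st.floats(-80, 80),
        p2=st.floats(-80, 80),
        r1=st.floats(0, 2e5),
        r2=st.floats(0, 2e5),
    )
    def test_matches_direct_complex_arithmetic(self, m1, m2, p1, p2, r1, r2):
        state = ImpedanceState(m1, p1, m2, p2, r1=r1, r2=r2)
        z1 = m1 * np.cos(np.deg2rad(p1)) + 1j * m1 * np.sin(np.deg2rad(p1)) + r1
        z2 = m2 * np.cos(np.deg2rad(p2)) + 1j * m2 * np.sin(np.deg2rad(p2)) + r2
        mag, phase = imbalance_indices(state)
        assert mag == pytest.approx(abs(abs(z1) - abs(z2)), rel=1e-9, abs=1e-9)
        expected_phase = abs(np.rad2deg(np.arctan2(z1.imag, z1.real) - np.arctan2(z2.imag, z2.real)))
        assert phase == pytest.approx(expected_phase, rel=1e-9, abs=1e-9)


class TestCommonModeCoupling:
    def test_ideal_amp_balanced_pair_couples_nothing(self):
        amp = AmplifierSpec(intrinsic_cmrr_db=np.inf)
        assert common_mode_coupling(balanced_state(), amp) == 0

    def test_intrinsic_cmrr_leakage(self):
        amp = AmplifierSpec(intrinsic_cmrr_db=100.0)
        g = common_mode_coupling(balanced_state(), amp)
        assert abs(g) == pytest.approx(1e-5, rel=1e-12)

    def test_gain_increases_with_complex_imbalance(self):
        amp = AmplifierSpec(intrinsic_cmrr_db=np.inf)
        gains = []
        for extra in (0.0, 5_000.0, 20_000.0):
            state = ImpedanceState(50_000, -20.0, 50_000 + extra, -20.0)
            gains.append(abs(common_mode_coupling(state, amp)))
        assert gains[0] < gains[1] < gains[2]

    def test_level3_couples_more_than_level1(self):
        amp = AmplifierSpec()
        assert abs(common_mode_coupling(mean_state(3), amp)) > abs(
            common_mode_coupling(mean_state(1), amp)
        )

    def test_low_input_impedance_rejected(self):
        with pytest.raises(ValueError):
            common_mode_coupling(balanced_state(), AmplifierSpec(input_impedance=1e6))


class TestSimulateMeasurement:
    filt = FilterChainSpec(fs=FS)
    amp = AmplifierSpec(input_impedance=1e8, intrinsic_cmrr_db=120.0)

    def test_zero_source_zero_interference_is_silent(self):
        quiet = InterferenceModel(harmonic_amplitudes={})
        out = simulate_measurement(flat_trace(), quiet, balanced_state(), self.amp, self.filt)
        assert np.allclose(out.samples, 0.0, atol=1e-12)

    def test_imbalance_raises_mains_harmonics_above_balanced_floor(self):
        intf = InterferenceModel(harmonic_amplitudes={50.0: 1.0, 100.0: 1.0})
        amp = AmplifierSpec(input_impedance=1e8, intrinsic_cmrr_db=np.inf)
        out_bal = simulate_measurement(flat_trace(), intf, balanced_state(), amp, self.filt)
        out_imb = simulate_measurement(flat_trace(), intf, mean_state(3), amp, self.filt)

        def power_at(trace, f0):
            f, p = periodogram(trace.samples[0], fs=FS)
            return p[np.argmin(np.abs(f - f0))]

        assert power_at(out_imb, 100.0) > 1e6 * max(power_at(out_bal, 100.0), 1e-30)

    def test_output_saturates_exactly_at_the_rails(self):
        big = MeasurementTrace(
            0.1 * np.sin(2 * np.pi * 100 * np.arange(3200) / FS)[None, :], FS
        )
        quiet = InterferenceModel(harmonic_amplitudes={})
        out = simulate_measurement(big, quiet, balanced_state(), self.amp, self.filt)
        assert np.abs(out.samples).max() == pytest.approx(9.0)
        assert np.all(np.abs(out.samples) <= 9.0)

    def test_linear_below_rails(self):
        raw = synth_source(SourceModel(), MotionLabel.CLOSE, 1.0, seed=3)
        # keep both the source and its double well inside the rails
        src = MeasurementTrace(0.1 * raw.samples, raw.fs)
        quiet = InterferenceModel(harmonic_amplitudes={})
        out1 = simulate_measurement(src, quiet, balanced_state(), self.amp, self.filt)
        doubled = MeasurementTrace(2 * src.samples, src.fs)
        out2 = simulate_measurement(doubled, quiet, balanced_state(), self.amp, self.filt)
        assert np.allclose(out2.samples, 2 * out1.samples, rtol=1e-9, atol=1e-12)

    def test_fs_mismatch_rejected(self):
        src = MeasurementTrace(np.zeros((1, 100)), 1000.0)
        with pytest.raises(ValueError):
            simulate_measurement(
                src, InterferenceModel(), balanced_state(), self.amp, self.filt
            )


class TestFilterChain:
    def test_notch_attenuates_50hz_by_30db(self):
        filt = FilterChainSpec(fs=FS)
        t = np.arange(16000) / FS
        tone = np.sin(2 * np.pi * 50 * t)[None, :]
        out = filt.apply(tone)
        mid = slice(4000, 12000)
        atten_db = 20 * np.log10(
            np.sqrt((out[:, mid] ** 2).mean()) / np.sqrt((tone[:, mid] ** 2).mean())
        )
        assert atten_db < -30

    @pytest.mark.parametrize("freq", [10.0, 100.0, 500.0])
    def test_passband_ripple_below_1db(self, freq):
        filt = FilterChainSpec(fs=FS)
        t = np.arange(16000) / FS
        tone = np.sin(2 * np.pi * freq * t)[None, :]
        out = filt.apply(tone)
        mid = slice(4000, 12000)
        gain_db = 20 * np.log10(
            np.sqrt((out[:, mid] ** 2).mean()) / np.sqrt((tone[:, mid] ** 2).mean())
        )
        assert abs(gain_db) < 1.0

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            FilterChainSpec(fs=FS, band_hz=(1000.0, 1.0))
        with pytest.raises(ValueError):
            FilterChainSpec(fs=FS, band_hz=(900.0, 1000.0))  # notch outside band


class TestMeterSchedule:
    amp = AmplifierSpec()

    def test_empty_schedule_is_a_no_op(self):
        trace = flat_trace(0.5)
        out = apply_meter_schedule(trace, InterferenceModel(), self.amp)
        assert np.array_equal(out.samples, trace.samples)
        assert not out.excluded_mask.any()

    def test_masked_fraction_matches_schedule_plus_margin(self):
        trace = flat_trace(0.0, n=8000)  # 5 s
        intf = InterferenceModel(meter_schedule=((1.0, 1.5),))
        out = apply_meter_schedule(trace, intf, self.amp, settle_s=0.05)
        expected = (0.5 + 2 * 0.05) * FS / 8000
        assert out.excluded_mask.mean() == pytest.approx(expected, abs=1e-3)

    def test_tone_drives_the_output_to_the_rails(self):
        trace = flat_trace(0.0, n=8000)
        intf = InterferenceModel(meter_schedule=((1.0, 2.0),))
        out = apply_meter_schedule(trace, intf, self.amp)
        inside = out.samples[0, int(1.1 * FS) : int(1.9 * FS)]
        # 1 Vrms x 40 dB preamp is two orders beyond the rails: nearly every
        # within-interval sample sits at +/-9 V
        assert np.abs(inside).max() == pytest.approx(9.0)
        assert (np.abs(inside) >= 8.99).mean() > 0.8
        outside = out.samples[0, : int(0.9 * FS)]
        assert np.allclose(outside, 0.0)

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError):
            InterferenceModel(meter_schedule=((0.0, 1.0), (0.5, 1.5)))


class TestExcludeSaturated:
    def test_below_threshold_leaves_mask_unchanged(self):
        trace = flat_trace(1.0)
        out = exclude_saturated(trace, threshold_v=8.9, min_run=10)
        assert not out.excluded_mask.any()

    def test_constructed_burst_is_masked_exactly(self):
        x = np.zeros((1, 1000))
        x[0, 300:500] = 9.0
        out = exclude_saturated(MeasurementTrace(x, FS), threshold_v=8.9, min_run=50)
        expected = np.zeros(1000, dtype=bool)
        expected[300:500] = True
        assert np.array_equal(out.excluded_mask, expected)

    def test_short_bursts_are_ignored(self):
        x = np.zeros((1, 1000))
        x[0, 100:120] = 9.0
        out = exclude_saturated(MeasurementTrace(x, FS), threshold_v=8.9, min_run=50)
        assert not out.excluded_mask.any()

    def test_matches_brute_force_run_scan(self, rng):
        x = rng.choice([0.0, 9.0], size=(1, 500), p=[0.7, 0.3])
        threshold, min_run = 8.5, 4
        out = exclude_saturated(MeasurementTrace(x, FS), threshold, min_run)
        # independent pure-python run-length scan
        expected = np.zeros(500, dtype=bool)
        run = 0
        for i in range(500):
            if abs(x[0, i]) >= threshold:
                run += 1
            else:
                if run >= min_run:
                    expected[i - run : i] = True
                run = 0
        if run >= min_run:
            expected[500 - run :] = True
        assert np.array_equal(out.excluded_mask, expected)
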