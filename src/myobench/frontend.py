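"""Measurement-electronics simulation for the sEMG bench.

Models the differential amplification chain used for myoelectric recording:
a 40 dB instrumentation preamplifier, a 1-1000 Hz band-pass filter, a 50 Hz
notch, a second gain stage, and +/-9 V output rails.  Common-mode
interference (mains radiation and its harmonics, plus the 300 Hz LCR-meter
tone) couples into the differential path through source-impedance imbalance:
the classic potential-divider mechanism by which unequal electrode-skin
impedances degrade the effective common-mode rejection ratio, plus a
residual intrinsic-CMRR leakage term of the amplifier itself.

The switched impedance-measurement protocol is also modelled: while the
meter's 1 Vrms tone is on, the preamplifier saturates hard (1 Vrms x 40 dB
is far beyond the 9 V rails), and those segments are excluded from analysis
via the trace's exclusion mask.

Note the sampled data cannot carry the analog low-pass edge: at a 1600 Hz
rate the 1000 Hz corner lies above Nyquist, so the digital filter chain
realizes the high-pass section only (the band edge is honored whenever the
rate allows it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .semg_synth import ImpedanceState
from .trace import MeasurementTrace

__all__ = [
    "AmplifierSpec",
    "FilterChainSpec",
    "InterferenceModel",
    "MeasurementTrace",
    "imbalance_indices",
    "common_mode_coupling",
    "simulate_measurement",
    "apply_meter_schedule",
    "exclude_saturated",
]


@dataclass
class AmplifierSpec:
    """Differential amplifier chain parameters.

    ``pre_gain_db`` is the instrumentation-amplifier gain (40 dB);
    ``second_gain_db`` the post-filter stage, chosen by default so a 1 mV RMS
    source spans roughly two thirds of the +/-``rail_v`` output range.
    ``input_impedance`` (Ohm, complex allowed) and ``intrinsic_cmrr_db`` are
    engineering defaults, not measured values; ``intrinsic_cmrr_db`` may be
    ``inf`` for an ideal amplifier.
    """

    pre_gain_db: float = 40.0
    second_gain_db: float = 36.0
    input_impedance: complex = 1e9
    intrinsic_cmrr_db: float = 100.0
    rail_v: float = 9.0

    def __post_init__(self) -> None:
        if self.pre_gain_db <= 0 or self.rail_v <= 0:
            raise ValueError("pre_gain_db and rail_v must be positive")
        if abs(self.input_impedance) == 0:
            raise ValueError("input impedance must be non-zero")

    @property
    def pre_gain(self) -> float:
        return 10 ** (self.pre_gain_db / 20)

    @property
    def second_gain(self) -> float:
        return 10 ** (self.second_gain_db / 20)


@dataclass
class FilterChainSpec:
    """Band-pass plus mains-notch filter chain.

    Default: 2nd-order Butterworth 1-1000 Hz band-pass and a Q=30 notch at
    50 Hz, both applied forward-backward (zero phase).  If the upper band
    edge is at or above Nyquist only the high-pass section is realized.
    """

    fs: float = 1600.0
    band_hz: tuple[float, float] = (1.0, 1000.0)
    order: int = 2
    notch_hz: float = 50.0
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError(f"invalid band edges {self.band_hz}")
        if lo >= self.fs / 2:
            raise ValueError("lower band edge must lie below Nyquist")
        if not (lo < self.notch_hz < min(hi, self.fs / 2)):
            raise ValueError("notch must lie inside the realized passband")

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Zero-phase band-pass (or high-pass) followed by the notch."""
        lo, hi = self.band_hz
        if hi >= self.fs / 2:
            sos = signal.butter(self.order, lo, btype="highpass", fs=self.fs, output="sos")
        else:
            sos = signal.butter(self.order, (lo, hi), btype="bandpass", fs=self.fs, output="sos")
        y = signal.sosfiltfilt(sos, x, axis=-1)
        b, a = signal.iirnotch(self.notch_hz, self.notch_q, fs=self.fs)
        return signal.filtfilt(b, a, y, axis=-1)


@dataclass
class InterferenceModel:
    """Common-mode interference: mains harmonics plus the LCR-meter tone.

    ``harmonic_amplitudes`` maps frequency (Hz) to peak common-mode volts at
    the body.  ``meter_schedule`` lists (start_s, end_s) intervals during
    which the meter drives its ``meter_tone_v`` Vrms tone at
    ``meter_tone_hz``; intervals must be disjoint.
    """

    mains_hz: float = 50.0
    harmonic_amplitudes: dict[float, float] = field(
        default_factory=lambda: {50.0: 1.3, 100.0: 0.8, 150.0: 0.25, 200.0: 0.8, 250.0: 0.25, 300.0: 0.8}
    )
    meter_tone_hz: float = 300.0
    meter_tone_v: float = 1.0  # Vrms
    meter_schedule: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.harmonic_amplitudes.values()):
            raise ValueError("harmonic amplitudes must be non-negative")
        ivals = sorted(self.meter_schedule)
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("meter schedule intervals must be disjoint")
        for s, e in ivals:
            if not (0 <= s < e):
                raise ValueError(f"invalid meter interval ({s}, {e})")

    def common_mode_waveform(self, times: np.ndarray) -> np.ndarray:
        """Mains-harmonic common-mode voltage at the given sample times."""
        v = np.zeros_like(times)
        for f, a in self.harmonic_amplitudes.items():
            if a > 0:
                v += a * np.sin(2 * np.pi * f * times)
        return v


def imbalance_indices(state: ImpedanceState) -> tuple[float, float]:
    """Magnitude and phase-angle imbalance of a source-impedance pair.

    Returns ``(| |Z1+R1| - |Z2+R2| |`` in Ohm, ``|arg(Z1+R1) - arg(Z2+R2)|``
    in degrees) — the two indices tabulated per noise level.  Note this is
    the difference of magnitudes, not the magnitude of the complex
    difference used by :func:`common_mode_coupling`.
    """
    z1, z2 = state.z1_total(), state.z2_total()
    mag_diff = abs(abs(z1) - abs(z2))
    phase_diff = abs(np.rad2deg(np.angle(z1) - np.angle(z2)))
    return float(mag_diff), float(phase_diff)


def common_mode_coupling(state: ImpedanceState, amp: AmplifierSpec) -> complex:
    """Common-mode to differential conversion gain.

    Potential-divider model: each input sees the common-mode voltage through
    its own source impedance against the amplifier input impedance, so

        g = Zin * (1/(Zin + Z1') - 1/(Zin + Z2')) + 10**(-CMRR/20)

    with ``Z1' = Z1 + R1`` and ``Z2' = Z2 + R2``.  |g| grows with the complex
    imbalance |Z2' - Z1'| for fixed Zin.
    """
    zin = complex(amp.input_impedance)
    if zin == 0:
        raise ValueError("degenerate zero input impedance")
    z1, z2 = state.z1_total(), state.z2_total()
    for z in (z1, z2):
        if abs(zin) / abs(z) <= 1e3:
            raise ValueError(
                "amplifier input impedance must exceed the source impedance "
                f"by >1000x (|Zin|={abs(zin):.3g}, |Z'|={abs(z):.3g})"
            )
    leak = 0.0 if np.isinf(amp.intrinsic_cmrr_db) else 10 ** (-amp.intrinsic_cmrr_db / 20)
    return zin * (1 / (zin + z1) - 1 / (zin + z2)) + leak


def simulate_measurement(
    diff_source: MeasurementTrace,
    common_mode: InterferenceModel,
    state: ImpedanceState,
    amp: AmplifierSpec,
    filt: FilterChainSpec,
) -> MeasurementTrace:
    """Run a differential source through the full amplification chain.

    output = clip( G2 * notch( bandpass( G1 * (v_diff + |g|*v_cm) ) ) )

    where ``g`` is the common-mode conversion gain for ``state`` and ``v_cm``
    the mains-harmonic interference waveform.  The meter tone is injected
    separately by :func:`apply_meter_schedule`.  Output never exceeds
    +/-``rail_v``.
    """
    if abs(filt.fs - diff_source.fs) > 1e-9:
        raise ValueError(
            f"filter chain fs {filt.fs} does not match trace fs {diff_source.fs}"
        )
    g = abs(common_mode_coupling(state, amp))
    v_cm = common_mode.common_mode_waveform(diff_source.times())
    pre = amp.pre_gain * (diff_source.samples + g * v_cm[None, :])
    out = np.clip(amp.second_gain * filt.apply(pre), -amp.rail_v, amp.rail_v)
    return MeasurementTrace(out, diff_source.fs, diff_source.channel_ids,
                            diff_source.excluded_mask.copy())


def apply_meter_schedule(
    trace: MeasurementTrace,
    interference: InterferenceModel,
    amp: AmplifierSpec,
    settle_s: float = 0.05,
) -> MeasurementTrace:
    """Inject the LCR-meter tone during its on-intervals and mask them.

    The 1 Vrms tone amplified by the full chain exceeds the rails by an
    order of magnitude, so within-interval samples clip at +/-``rail_v``.
    The exclusion mask is set on each interval extended by ``settle_s`` on
    both sides (conservative settling margin).
    """
    out = trace.copy()
    n = out.n_samples
    t = out.times()
    tone_peak = interference.meter_tone_v * np.sqrt(2) * amp.pre_gain * amp.second_gain
    for start_s, end_s in interference.meter_schedule:
        if end_s > trace.duration_s + 1e-9:
            raise ValueError(f"meter interval ({start_s}, {end_s}) exceeds the trace")
        i0, i1 = int(round(start_s * out.fs)), min(int(round(end_s * out.fs)), n)
        tone = tone_peak * np.sin(2 * np.pi * interference.meter_tone_hz * t[i0:i1])
        out.samples[:, i0:i1] = np.clip(
            out.samples[:, i0:i1] + tone[None, :], -amp.rail_v, amp.rail_v
        )
        m0 = max(int(round((start_s - settle_s) * out.fs)), 0)
        m1 = min(int(round((end_s + settle_s) * out.fs)), n)
        out.excluded_mask[m0:m1] = True
    return out


def exclude_saturated(
    trace: MeasurementTrace, threshold_v: float, min_run: int
) -> MeasurementTrace:
    """Mask sustained saturation: runs of >= ``min_run`` samples at the rails.

    A sample counts as saturated when ``|v| >= threshold_v`` on any channel;
    only runs of at least ``min_run`` consecutive saturated samples are added
    to the exclusion mask (already-excluded samples stay excluded).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    out = trace.copy()
    hot = np.any(np.abs(out.samples) >= threshold_v, axis=0)
    # run-length encode the saturated indicator
    edges = np.flatnonzero(np.diff(np.concatenate(([0], hot.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            out.excluded_mask[start:stop] = True
    return out
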