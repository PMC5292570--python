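"""Synthetic surface-EMG sources, electrode-transfer variants, impedance states.

Surface EMG recorded over forearm muscles is well approximated, for bench
purposes, by a band-limited stochastic carrier (roughly 20-450 Hz) whose
amplitude is modulated by muscle activation: sub-millivolt RMS at the skin,
with each hand/wrist motion activating the three recording channels in a
distinct pattern.  This module generates such signals, applies
electrode-dependent linear transfer differences (gelled Ag/AgCl "wet"
electrodes vs dry polypyrrole-coated fabric "PPy" electrodes), and draws
complex source-impedance states whose magnitude/phase imbalance statistics
match the three measured rest-noise levels.

Everything here is deterministic given a seed: the same seed and parameters
produce bit-identical traces.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .trace import MeasurementTrace

__all__ = [
    "MotionLabel",
    "SourceModel",
    "ElectrodeTransfer",
    "ImpedanceState",
    "NoiseLevelSpec",
    "TABLE3_LEVEL_SPECS",
    "WET_TRANSFER",
    "PPY_TRANSFER",
    "synth_source",
    "apply_electrode",
    "draw_impedance_state",
    "draw_impedance_states",
    "validate_level_table",
]


class MotionLabel(enum.IntEnum):
    """The five motion classes used for myoelectric control.

    ``RELAX`` is the designated rest class; the remaining four are the
    prosthesis commands (hand close/open, wrist flexion/extension).
    """

    RELAX = 0
    CLOSE = 1
    OPEN = 2
    FLEXION = 3
    EXTENSION = 4


# Per-motion, per-channel activation amplitudes (volts RMS at the skin).
# Each active motion has a distinct dominant channel so the 5-class problem
# is separable by design; rest sits at 1% of the strongest activation.
_DEFAULT_ENVELOPE: dict[MotionLabel, tuple[float, float, float]] = {
    MotionLabel.RELAX: (1e-5, 1e-5, 1e-5),
    MotionLabel.CLOSE: (1.0e-3, 4.0e-4, 1.5e-4),
    MotionLabel.OPEN: (1.5e-4, 1.0e-3, 4.0e-4),
    MotionLabel.FLEXION: (4.0e-4, 1.5e-4, 1.0e-3),
    MotionLabel.EXTENSION: (7.0e-4, 7.0e-4, 1.0e-4),
}


@dataclass
class SourceModel:
    """Generative model for multi-channel sEMG at the skin surface.

    The carrier is Gaussian white noise band-pass filtered to
    ``carrier_band`` (4th-order Butterworth, zero-phase), normalized to unit
    RMS per channel and scaled by the per-motion envelope amplitude.  Onset
    is smoothed with a raised-cosine ramp of ``envelope_rise_ms``.
    """

    n_channels: int = 3
    fs: float = 1600.0
    carrier_band: tuple[float, float] = (20.0, 450.0)
    envelope: dict[MotionLabel, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_ENVELOPE)
    )
    envelope_rise_ms: float = 50.0

    def __post_init__(self) -> None:
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(
                f"carrier band {self.carrier_band} must lie within (0, fs/2)"
            )
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        amps = {m: np.asarray(a, dtype=float) for m, a in self.envelope.items()}
        for m, a in amps.items():
            if a.shape != (self.n_channels,):
                raise ValueError(f"envelope for {m!s} must have {self.n_channels} entries")
            if np.any(a < 0):
                raise ValueError("activation amplitudes must be non-negative")
        if MotionLabel.RELAX in amps:
            active_max = max(
                (a.max() for m, a in amps.items() if m != MotionLabel.RELAX),
                default=0.0,
            )
            if active_max > 0 and amps[MotionLabel.RELAX].max() > 0.05 * active_max:
                raise ValueError(
                    "rest-class activation must be <= 5% of the strongest "
                    "active-class activation"
                )


@dataclass
class ElectrodeTransfer:
    """Linear electrode-dependent transfer applied to a skin-surface trace.

    ``gain_scale`` is a broadband multiplier; ``hf_tilt_db`` adds a relative
    shelf above ``hf_pivot_hz`` (PPy fabric electrodes show relatively more
    power above ~150 Hz than gelled Ag/AgCl); ``noise_density`` adds white
    measurement noise in V/sqrt(Hz).
    """

    gain_scale: float = 1.0
    hf_tilt_db: float = 0.0
    hf_pivot_hz: float = 150.0
    noise_density: float = 0.0

    def __post_init__(self) -> None:
        if self.gain_scale <= 0:
            raise ValueError("gain_scale must be positive")
        if self.hf_pivot_hz <= 0:
            raise ValueError("hf_pivot_hz must be positive")
        if self.noise_density < 0:
            raise ValueError("noise_density must be non-negative")


#: Default electrode pair: the wet electrode reads slightly larger broadband
#: amplitude; the dry PPy electrode carries relatively more power above 150 Hz.
WET_TRANSFER = ElectrodeTransfer(gain_scale=1.1, hf_tilt_db=0.0)
PPY_TRANSFER = ElectrodeTransfer(gain_scale=1.0, hf_tilt_db=3.0, hf_pivot_hz=150.0)


@dataclass
class ImpedanceState:
    """Complex source impedances of one differential pair, plus trim resistors.

    ``z1``/``z2`` lump tissue, skin-electrode interface, and electrode
    impedance, represented by their 300 Hz magnitude/phase; ``r1``/``r2`` are
    the series variable resistors (0-200 kOhm) used to unbalance the pair.
    """

    z1_mag: float
    z1_phase: float
    z2_mag: float
    z2_phase: float
    r1: float = 0.0
    r2: float = 0.0

    def __post_init__(self) -> None:
        if self.z1_mag <= 0 or self.z2_mag <= 0:
            raise ValueError("impedance magnitudes must be positive")
        for r in (self.r1, self.r2):
            if not 0 <= r <= 200_000:
                raise ValueError("trim resistances must lie in [0, 200000] Ohm")

    def z1_total(self) -> complex:
        """Z1 + R1 as a complex impedance."""
        return self.z1_mag * np.exp(1j * np.deg2rad(self.z1_phase)) + self.r1

    def z2_total(self) -> complex:
        """Z2 + R2 as a complex impedance."""
        return self.z2_mag * np.exp(1j * np.deg2rad(self.z2_phase)) + self.r2


@dataclass
class NoiseLevelSpec:
    """Imbalance statistics of one rest-noise level.

    ``mag_diff_mean``/``mag_diff_sd`` summarize | |Z1'| - |Z2'| | in Ohm,
    ``phase_diff_mean``/``phase_diff_sd`` the absolute phase-angle difference
    in degrees, at 300 Hz.  Draws come from zero-truncated normals whose
    first two moments match these values where that is achievable (see
    :func:`draw_impedance_states`).
    """

    level: int
    mag_diff_mean: float
    mag_diff_sd: float
    phase_diff_mean: float
    phase_diff_sd: float
    baseline_mag: float = 50_000.0
    baseline_phase: float = -20.0

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError("level must be 1, 2 or 3")
        if self.mag_diff_mean < 0 or self.phase_diff_mean < 0:
            raise ValueError("imbalance means must be non-negative")
        if self.mag_diff_sd < 0 or self.phase_diff_sd < 0:
            raise ValueError("imbalance SDs must be non-negative")


#: Level-wise imbalance statistics measured at 300 Hz / 1 Vrms (mean and
#: sample SD of magnitude and phase-angle differences over 10 repeats each).
TABLE3_LEVEL_SPECS: dict[int, NoiseLevelSpec] = {
    1: NoiseLevelSpec(1, 1560.0, 1047.0, 1.2, 1.3),
    2: NoiseLevelSpec(2, 7880.0, 1320.0, 8.9, 3.2),
    3: NoiseLevelSpec(3, 21250.0, 6734.0, 33.2, 9.8),
}


def validate_level_table(specs: dict[int, NoiseLevelSpec]) -> None:
    """Check that imbalance means strictly increase with noise level."""
    levels = sorted(specs)
    for lo, hi in zip(levels, levels[1:]):
        a, b = specs[lo], specs[hi]
        if not (b.mag_diff_mean > a.mag_diff_mean and b.phase_diff_mean > a.phase_diff_mean):
            raise ValueError(
                f"imbalance means must increase with level ({lo} -> {hi})"
            )


validate_level_table(TABLE3_LEVEL_SPECS)


def synth_source(
    model: SourceModel,
    motion: MotionLabel,
    duration_s: float,
    seed: int,
) -> MeasurementTrace:
    """Generate a multi-channel sEMG trace for one motion class.

    After the onset ramp each channel's RMS equals the configured envelope
    amplitude for ``motion`` (the carrier is renormalized over the
    post-onset region), and >90% of signal power lies inside
    ``model.carrier_band``.

    Raises ``ValueError`` for non-positive duration or a motion absent from
    the envelope map.
    """
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    if motion not in model.envelope:
        raise ValueError(f"no envelope configured for motion {motion!r}")

    n = int(round(model.fs * duration_s))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((model.n_channels, n))
    sos = signal.butter(4, model.carrier_band, btype="bandpass", fs=model.fs, output="sos")
    carrier = signal.sosfiltfilt(sos, white, axis=1)

    n_rise = min(int(round(model.envelope_rise_ms * model.fs / 1000)), n)
    # unit RMS over the post-onset region, so amplitudes are exact there
    steady = carrier[:, n_rise:] if n_rise < n else carrier
    rms = np.sqrt(np.mean(steady**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    carrier = carrier / rms

    ramp = np.ones(n)
    if n_rise > 0:
        ramp[:n_rise] = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / n_rise))

    amps = np.asarray(model.envelope[motion], dtype=float)[:, None]
    return MeasurementTrace(carrier * amps * ramp[None, :], model.fs)


def apply_electrode(
    trace: MeasurementTrace,
    transfer: ElectrodeTransfer,
    seed: int | None = None,
) -> MeasurementTrace:
    """Apply an electrode transfer (gain, high-frequency shelf, noise).

    With ``hf_tilt_db = 0`` and ``noise_density = 0`` the output is exactly
    ``gain_scale`` times the input.  The shelf multiplies spectral content at
    and above ``hf_pivot_hz`` by ``10**(hf_tilt_db/20)`` (zero-phase,
    frequency-domain).  White noise of RMS ``noise_density*sqrt(fs/2)`` is
    added when ``noise_density > 0`` (requires a seed).
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if transfer.hf_pivot_hz >= trace.fs / 2:
        raise ValueError("hf_pivot_hz must lie below the Nyquist frequency")

    x = trace.samples * transfer.gain_scale
    if transfer.hf_tilt_db != 0.0:
        n = trace.n_samples
        spec = np.fft.rfft(x, axis=1)
        freqs = np.fft.rfftfreq(n, d=1.0 / trace.fs)
        h = np.where(freqs >= transfer.hf_pivot_hz, 10 ** (transfer.hf_tilt_db / 20), 1.0)
        x = np.fft.irfft(spec * h[None, :], n=n, axis=1)
    if transfer.noise_density > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_density > 0")
        rng = np.random.default_rng(seed)
        noise_rms = transfer.noise_density * np.sqrt(trace.fs / 2)
        x = x + noise_rms * rng.standard_normal(x.shape)
    return MeasurementTrace(x, trace.fs, trace.channel_ids, trace.excluded_mask.copy())


def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal with the given moments.

    A normal truncated below at zero always has mean/SD > 1; when the target
    ratio allows it, we solve for the parent parameters so the *truncated*
    distribution has exactly the requested mean and SD.  Otherwise (ratio
    <= 1, e.g. the level-1 phase column) we fall back to direct truncation
    of N(mean, sd), whose realized mean sits somewhat above ``mean``.
    """
    if sd == 0:
        return mean, 0.0
    ratio = mean / sd

    def moments(alpha: float) -> tuple[float, float]:
        lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        m = lam - alpha
        v = 1 + alpha * lam - lam**2
        return m, v

    def f(alpha: float) -> float:
        m, v = moments(alpha)
        return m / np.sqrt(v) - ratio

    if ratio <= 1.0 + 1e-9 or f(-40.0) * f(20.0) > 0:
        return mean, sd  # direct truncation fallback
    alpha = optimize.brentq(f, -40.0, 20.0, xtol=1e-12)
    m, v = moments(alpha)
    sigma = sd / np.sqrt(v)
    mu = -alpha * sigma
    return mu, sigma


def _draw_truncated(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    mu, sigma = _truncnorm_params(mean, sd)
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def draw_impedance_states(
    spec: NoiseLevelSpec, n: int, seed: int
) -> list[ImpedanceState]:
    """Draw ``n`` impedance states whose imbalance follows ``spec``.

    Magnitude and phase differences are drawn independently from
    zero-truncated normals (moment-matched to the spec's mean/SD where
    achievable) and split symmetrically about the baseline impedance
    (default 50 kOhm at -20 deg), so ``frontend.imbalance_indices`` recovers
    the drawn differences exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dmag = _draw_truncated(spec.mag_diff_mean, spec.mag_diff_sd, n, rng)
    dphase = _draw_truncated(spec.phase_diff_mean, spec.phase_diff_sd, n, rng)
    # keep both magnitudes positive even for extreme draws
    dmag = np.minimum(dmag, 1.8 * spec.baseline_mag)
    states = []
    for dm, dp in zip(dmag, dphase):
        states.append(
            ImpedanceState(
                z1_mag=spec.baseline_mag - dm / 2,
                z1_phase=spec.baseline_phase + dp / 2,
                z2_mag=spec.baseline_mag + dm / 2,
                z2_phase=spec.baseline_phase - dp / 2,
            )
        )
    return states


def draw_impedance_state(spec: NoiseLevelSpec, seed: int) -> ImpedanceState:
    """Draw a single impedance state (see :func:`draw_impedance_states`)."""
    return draw_impedance_states(spec, 1, seed)[0]
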