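"""Evaluation computations: RMS envelopes, correlation, summaries, spectra.

These are the descriptive analyses used to compare electrode types and
noise conditions: sliding-window RMS envelopes and their Pearson
correlation between simultaneously recorded electrode views; mean/sample-SD
summaries of correlation coefficients and impedance imbalances; overall
accuracy means of the pattern-recognition table; rest-state noise-level
classification from output amplitude; and band-power comparisons around a
150 Hz split.

One transcription note: the reference level-1 phase-angle column prints a
mean of 1.2 deg while its ten listed values average 1.14 — the fixture
comparison for that single cell therefore carries a +/-0.1 deg tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .trace import MeasurementTrace

__all__ = [
    "CorrelationResult",
    "ImbalanceSummary",
    "NoiseLevelThresholds",
    "rms_envelope",
    "pearson_corr",
    "summarize",
    "accuracy_summary",
    "classify_noise_level",
    "band_power_compare",
    "harmonic_band_power",
    "round_half_away",
]


@dataclass
class CorrelationResult:
    """Pearson correlation between two RMS envelopes."""

    r: float
    n_samples: int
    window_ms: float = float("nan")

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError(f"correlation coefficient out of range: {self.r}")


@dataclass
class ImbalanceSummary:
    """Mean/SD of magnitude (Ohm) and phase (deg) imbalance at one level."""

    level: int
    mag_mean: float
    mag_sd: float
    phase_mean: float
    phase_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n >= 2 and (self.mag_sd < 0 or self.phase_sd < 0):
            raise ValueError("SD must be non-negative")


@dataclass
class NoiseLevelThresholds:
    """Rest-state output-amplitude bands defining noise levels 1-3.

    Level 1: little noise (peak below ``v_lo``); level 2: excursions within
    the +/-``v_mid`` band; level 3: excursions reaching the +/-``v_rail``
    band.  ``v_lo`` is a package default (the reference only shows "little
    noise"), and nothing quantitative depends on it.
    """

    v_lo: float = 1.5
    v_mid: float = 6.0
    v_rail: float = 9.0

    def __post_init__(self) -> None:
        if not 0 < self.v_lo < self.v_mid < self.v_rail:
            raise ValueError("thresholds must satisfy 0 < v_lo < v_mid < v_rail")


def rms_envelope(
    trace: MeasurementTrace,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
) -> MeasurementTrace:
    """Sliding-window RMS amplitude of each channel.

    Windows advance by ``step_ms``; excluded samples are skipped inside each
    window (a window with no usable sample yields NaN).  The returned trace
    is sampled at ``1000/step_ms`` Hz.  A constant input ``c`` gives an
    envelope of ``|c|`` everywhere.
    """
    win = int(round(window_ms * trace.fs / 1000))
    step = int(round(step_ms * trace.fs / 1000))
    if win < 1 or step < 1:
        raise ValueError("window and step must be at least one sample")
    if win > trace.n_samples:
        raise ValueError("RMS window longer than the trace")
    good = ~trace.excluded_mask
    sq = trace.samples**2
    starts = np.arange(0, trace.n_samples - win + 1, step)
    env = np.empty((trace.n_channels, len(starts)))
    for j, s in enumerate(starts):
        m = good[s : s + win]
        if m.any():
            env[:, j] = np.sqrt(sq[:, s : s + win][:, m].mean(axis=1))
        else:
            env[:, j] = np.nan
    return MeasurementTrace(env, 1000.0 / step_ms, trace.channel_ids)


def _as_values(x: MeasurementTrace | np.ndarray) -> np.ndarray:
    if isinstance(x, MeasurementTrace):
        return x.samples.ravel()
    return np.asarray(x, dtype=float).ravel()


def pearson_corr(
    x: MeasurementTrace | np.ndarray, y: MeasurementTrace | np.ndarray
) -> CorrelationResult:
    """Pearson product-moment correlation between two envelopes.

    Multi-channel envelopes are compared sample-by-sample across all
    channels; NaN pairs (fully excluded windows) are dropped.  Zero variance
    in either argument is an error.
    """
    xv, yv = _as_values(x), _as_values(y)
    if xv.shape != yv.shape:
        raise ValueError("envelopes must have equal length")
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    if xv.size < 2:
        raise ValueError("need at least two paired samples")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = _stats.pearsonr(xv, yv).statistic
    return CorrelationResult(r=float(r), n_samples=int(xv.size))


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    SD is NaN for a single value.  No rounding is applied here; rounding to
    the printed precision happens only at comparison/presentation time.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    return mean, sd


def accuracy_summary(table: pd.DataFrame) -> dict[str, pd.Series | pd.DataFrame]:
    """Unweighted means of a task x subject x condition accuracy table.

    ``table`` is long-format with columns ``task``, ``subject``,
    ``condition``, ``accuracy`` (percent) and must be complete (every
    task/subject/condition cell present exactly once).  Returns per-task
    means, per-subject means, and the overall mean, each by condition.
    """
    required = {"task", "subject", "condition", "accuracy"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(
        index=["task", "subject"], columns="condition", values="accuracy",
        aggfunc="first", sort=False,
    )
    if wide.isna().any().any():
        raise ValueError("accuracy table has missing cells")
    n_cells = table[["task", "subject", "condition"]].drop_duplicates().shape[0]
    if n_cells != len(table):
        raise ValueError("accuracy table has duplicate cells")
    per_task = wide.groupby(level="task", sort=False).mean()
    per_subject = wide.groupby(level="subject", sort=False).mean()
    overall = wide.mean()
    return {"per_task": per_task, "per_subject": per_subject, "overall": overall}


def classify_noise_level(
    rest_trace: MeasurementTrace,
    thr: NoiseLevelThresholds | None = None,
) -> int:
    """Classify a rest-state recording into noise level 1, 2 or 3.

    Level 1 if the peak absolute output stays below ``v_lo``; level 3 if it
    reaches the band at or beyond ``v_mid`` (up to the rails); level 2
    otherwise.  Excluded samples are ignored.
    """
    thr = thr or NoiseLevelThresholds()
    good = ~rest_trace.excluded_mask
    if not good.any():
        raise ValueError("trace has no usable samples")
    peak = float(np.abs(rest_trace.samples[:, good]).max())
    if peak < thr.v_lo:
        return 1
    if peak >= thr.v_mid:
        return 3
    return 2


def band_power_compare(
    trace_a: MeasurementTrace,
    trace_b: MeasurementTrace,
    split_hz: float = 150.0,
) -> dict[str, float]:
    """Power below/above a split frequency for two traces, and their ratios.

    Periodogram power is integrated below and above ``split_hz`` (all
    channels pooled).  Returns the four band powers plus the B/A ratios per
    band — e.g. a dry-electrode view of a source shows a larger above-150 Hz
    ratio than below when its transfer boosts high frequencies.
    """
    if abs(trace_a.fs - trace_b.fs) > 1e-9:
        raise ValueError("traces must share a sampling rate")
    if not 0 < split_hz < trace_a.fs / 2:
        raise ValueError("split frequency must lie in (0, Nyquist)")

    def bands(trace: MeasurementTrace) -> tuple[float, float]:
        f, p = _signal.periodogram(trace.samples, fs=trace.fs, axis=-1)
        p = p.sum(axis=0)
        return float(p[f < split_hz].sum()), float(p[f >= split_hz].sum())

    a_lo, a_hi = bands(trace_a)
    b_lo, b_hi = bands(trace_b)
    return {
        "a_below": a_lo,
        "a_above": a_hi,
        "b_below": b_lo,
        "b_above": b_hi,
        "ratio_below": b_lo / a_lo if a_lo else float("inf"),
        "ratio_above": b_hi / a_hi if a_hi else float("inf"),
    }


def harmonic_band_power(
    trace: MeasurementTrace,
    freqs_hz: tuple[float, ...] = (100.0, 150.0, 200.0, 250.0, 300.0),
    half_width_hz: float = 2.0,
) -> float:
    """Summed periodogram power in narrow bands around interference tones.

    Default bands cover the mains harmonics that survive the 50 Hz notch
    plus the 300 Hz meter frequency.  Excluded samples are dropped before
    the periodogram (the remaining samples are concatenated).
    """
    good = ~trace.excluded_mask
    if not good.any():
        raise ValueError("trace has no usable samples")
    x = trace.samples[:, good]
    f, p = _signal.periodogram(x, fs=trace.fs, axis=-1)
    p = p.sum(axis=0)
    total = 0.0
    for f0 in freqs_hz:
        band = (f >= f0 - half_width_hz) & (f <= f0 + half_width_hz)
        total += float(p[band].sum())
    return total


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)
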