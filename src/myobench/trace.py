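"""Sampled multi-channel voltage traces with per-sample exclusion masks.

A :class:`MeasurementTrace` is the container every stage of the bench passes
around: raw synthetic sEMG at the skin, electrode-transformed views, and
amplified/filtered frontend output.  The exclusion mask marks samples that
must be skipped by downstream analysis (e.g. amplifier-saturated segments
recorded while the LCR meter tone was on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MeasurementTrace"]


@dataclass
class MeasurementTrace:
    """Multi-channel voltage time series.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, volts.  A 1-D array is
        promoted to one channel.
    fs
        Sampling rate in Hz, > 0.
    channel_ids
        Optional channel names; defaults to ``ch1..chN``.
    excluded_mask
        Per-sample boolean, ``True`` where the sample is excluded from
        analysis.  Shared across channels.
    """

    samples: np.ndarray
    fs: float
    channel_ids: tuple[str, ...] = ()
    excluded_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("trace must contain at least one sample")
        n_ch = self.samples.shape[0]
        if not self.channel_ids:
            self.channel_ids = tuple(f"ch{i + 1}" for i in range(n_ch))
        elif len(self.channel_ids) != n_ch:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {n_ch} channels"
            )
        if self.excluded_mask is None:
            self.excluded_mask = np.zeros(self.samples.shape[1], dtype=bool)
        else:
            self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
            if self.excluded_mask.shape != (self.samples.shape[1],):
                raise ValueError("exclusion mask length must match samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "MeasurementTrace":
        return MeasurementTrace(
            self.samples.copy(),
            self.fs,
            self.channel_ids,
            self.excluded_mask.copy(),
        )
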