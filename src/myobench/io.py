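"""Trace file I/O: CSV/TSV with a metadata header, and 16-bit WAV.

The text dialect is fixed to avoid locale drift: comma (or tab) separated,
period decimal separator, and '#'-prefixed metadata lines carrying the
sampling rate and channel names::

    # fs=1600
    # channels=ch1,ch2,ch3
    ch1,ch2,ch3,excluded
    0.0001,-0.0002,0.0,0
    ...

The optional ``excluded`` column stores the per-sample exclusion mask.
CSV/TSV round-trips are exact (17 significant digits); WAV round-trips are
exact to one 16-bit quantization step of the chosen full-scale voltage.
WAV files carry samples and rate only (no exclusion mask).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .trace import MeasurementTrace

__all__ = ["read_signal", "write_signal"]

_MASK_COLUMN = "excluded"


def write_signal(
    trace: MeasurementTrace,
    path: str | Path,
    fmt: str | None = None,
    wav_full_scale: float = 9.0,
) -> Path:
    """Write a trace to CSV, TSV or 16-bit WAV (format from the extension).

    ``wav_full_scale`` maps volts to the int16 range for WAV output (the
    +/-9 V amplifier rails by default).
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        cols = list(trace.channel_ids) + [_MASK_COLUMN]
        with open(path, "w") as fh:
            fh.write(f"# fs={trace.fs:.17g}\n")
            fh.write(f"# channels={','.join(trace.channel_ids)}\n")
            fh.write(sep.join(cols) + "\n")
            for i in range(trace.n_samples):
                row = [f"{v:.17g}" for v in trace.samples[:, i]]
                row.append(str(int(trace.excluded_mask[i])))
                fh.write(sep.join(row) + "\n")
    elif fmt == "wav":
        scaled = np.clip(trace.samples / wav_full_scale, -1.0, 1.0)
        data = np.round(scaled * 32767).astype(np.int16).T  # frames x channels
        wavfile.write(path, int(round(trace.fs)), data)
    else:
        raise ValueError(f"unsupported signal format {fmt!r}")
    return path


def read_signal(
    path: str | Path,
    fmt: str | None = None,
    wav_full_scale: float = 9.0,
) -> MeasurementTrace:
    """Read a trace written by :func:`write_signal`.

    CSV/TSV headers must carry a positive ``fs``; malformed or missing
    metadata raises ``ValueError``.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "wav":
        fs, data = wavfile.read(path)
        if data.ndim == 1:
            data = data[:, None]
        samples = data.T.astype(float) / 32767 * wav_full_scale
        return MeasurementTrace(samples, float(fs))
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unsupported signal format {fmt!r}")

    sep = "," if fmt == "csv" else "\t"
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line.lstrip("# ").partition("=")
        meta[key.strip()] = value.strip()
    if "fs" not in meta:
        raise ValueError(f"{path}: missing '# fs=' header")
    try:
        fs = float(meta["fs"])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed sampling rate {meta['fs']!r}") from exc
    if fs <= 0:
        raise ValueError(f"{path}: sampling rate must be positive, got {fs}")

    if body_start >= len(lines):
        raise ValueError(f"{path}: no column header")
    columns = lines[body_start].split(sep)
    rows = [line.split(sep) for line in lines[body_start + 1 :] if line]
    if any(len(r) != len(columns) for r in rows):
        raise ValueError(f"{path}: ragged rows (length mismatch with header)")
    if not rows:
        raise ValueError(f"{path}: no samples")
    data = np.asarray(rows, dtype=float).T

    if columns and columns[-1] == _MASK_COLUMN:
        mask = data[-1].astype(bool)
        samples, channels = data[:-1], columns[:-1]
    else:
        mask, samples, channels = None, data, columns
    if "channels" in meta:
        declared = tuple(meta["channels"].split(","))
        if list(declared) != channels:
            raise ValueError(f"{path}: channel header/body mismatch")
        channels = list(declared)
    return MeasurementTrace(samples, fs, tuple(channels), mask)
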