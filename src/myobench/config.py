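"""Experiment configuration: defaults, YAML loading, seed derivation.

An :class:`ExperimentConfig` bundles every stage's parameters (source model,
electrode pair, noise-level table, amplifier, filters, epoching, features,
training, session protocol).  YAML files override defaults section by
section; unknown keys are rejected so typos fail loudly.

One global seed fans out to per-stage child seeds through
:func:`derive_seed`, which hashes the stage tags into a
``numpy.random.SeedSequence`` — so any stage can be re-run in isolation
with a reproducible stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .analysis import NoiseLevelThresholds
from .frontend import AmplifierSpec, FilterChainSpec, InterferenceModel
from .pipeline import EpochConfig, FeatureSpec, TrainParams
from .semg_synth import (
    PPY_TRANSFER,
    TABLE3_LEVEL_SPECS,
    WET_TRANSFER,
    ElectrodeTransfer,
    MotionLabel,
    NoiseLevelSpec,
    SourceModel,
    validate_level_table,
)

__all__ = [
    "SessionSpec",
    "ExperimentConfig",
    "default_config",
    "load_config",
    "config_hash",
    "derive_seed",
]


@dataclass
class SessionSpec:
    """Synthetic session protocol: training length and test repetitions."""

    train_s: float = 8.0
    test_reps: int = 3
    test_s: float = 2.0

    def __post_init__(self) -> None:
        if self.train_s <= 0 or self.test_s <= 0 or self.test_reps < 1:
            raise ValueError("session durations and repetitions must be positive")


def _bench_amplifier() -> AmplifierSpec:
    # Bench values: a 100 MOhm effective common-mode input impedance and
    # 120 dB intrinsic CMRR keep the potential-divider term dominant across
    # all three imbalance levels, which is what separates the three
    # rest-noise output bands.  Defaults on AmplifierSpec itself stay at the
    # generic 1 GOhm / 100 dB.
    return AmplifierSpec(input_impedance=1e8, intrinsic_cmrr_db=120.0)


@dataclass
class ExperimentConfig:
    """Full parameter set for the synthetic bench."""

    seed: int = 1
    source: SourceModel = field(default_factory=SourceModel)
    electrodes: dict[str, ElectrodeTransfer] = field(
        default_factory=lambda: {
            "wet": dataclasses.replace(WET_TRANSFER, noise_density=2e-7),
            "ppy": dataclasses.replace(PPY_TRANSFER, noise_density=2e-7),
        }
    )
    noise_levels: dict[int, NoiseLevelSpec] = field(
        default_factory=lambda: dict(TABLE3_LEVEL_SPECS)
    )
    amplifier: AmplifierSpec = field(default_factory=_bench_amplifier)
    filter: FilterChainSpec = field(default_factory=FilterChainSpec)
    interference: InterferenceModel = field(default_factory=InterferenceModel)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    train: TrainParams = field(default_factory=TrainParams)
    session: SessionSpec = field(default_factory=SessionSpec)
    thresholds: NoiseLevelThresholds = field(default_factory=NoiseLevelThresholds)
    out_dir: str = "bench_out"

    def __post_init__(self) -> None:
        validate_level_table(self.noise_levels)
        if abs(self.source.fs - self.filter.fs) > 1e-9 or abs(
            self.source.fs - self.epochs.fs
        ) > 1e-9:
            raise ValueError("source, filter and epoch sampling rates must agree")


def default_config(seed: int = 1) -> ExperimentConfig:
    return ExperimentConfig(seed=seed)


def _strict(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {context!r}")
    return cls(**data)


def _parse_envelope(raw: dict) -> dict[MotionLabel, tuple[float, ...]]:
    env = {}
    for name, amps in raw.items():
        try:
            label = MotionLabel[name.upper()]
        except KeyError as exc:
            raise ValueError(f"unknown motion label {name!r} in envelope") from exc
        env[label] = tuple(float(a) for a in amps)
    return env


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML experiment config, overriding defaults section-wise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")

    sections = {
        "source", "electrodes", "noise_levels", "amplifier", "filter",
        "interference", "epochs", "features", "train", "session",
        "thresholds", "seed", "out_dir",
    }
    unknown = set(raw) - sections
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}")

    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        kwargs["out_dir"] = str(raw["out_dir"])
    if "source" in raw:
        src = dict(raw["source"])
        if "envelope" in src:
            src["envelope"] = _parse_envelope(src["envelope"])
        if "carrier_band" in src:
            src["carrier_band"] = tuple(src["carrier_band"])
        kwargs["source"] = _strict(SourceModel, src, "source")
    if "electrodes" in raw:
        kwargs["electrodes"] = {
            name: _strict(ElectrodeTransfer, dict(params), f"electrodes.{name}")
            for name, params in raw["electrodes"].items()
        }
    if "noise_levels" in raw:
        kwargs["noise_levels"] = {
            int(level): _strict(
                NoiseLevelSpec, {"level": int(level), **dict(params)},
                f"noise_levels.{level}",
            )
            for level, params in raw["noise_levels"].items()
        }
    if "amplifier" in raw:
        kwargs["amplifier"] = _strict(AmplifierSpec, dict(raw["amplifier"]), "amplifier")
    if "filter" in raw:
        filt = dict(raw["filter"])
        if "band_hz" in filt:
            filt["band_hz"] = tuple(filt["band_hz"])
        kwargs["filter"] = _strict(FilterChainSpec, filt, "filter")
    if "interference" in raw:
        intf = dict(raw["interference"])
        if "harmonic_amplitudes" in intf:
            intf["harmonic_amplitudes"] = {
                float(f): float(a) for f, a in intf["harmonic_amplitudes"].items()
            }
        if "meter_schedule" in intf:
            intf["meter_schedule"] = tuple(tuple(iv) for iv in intf["meter_schedule"])
        kwargs["interference"] = _strict(InterferenceModel, intf, "interference")
    if "epochs" in raw:
        kwargs["epochs"] = _strict(EpochConfig, dict(raw["epochs"]), "epochs")
    if "features" in raw:
        feat = dict(raw["features"])
        if "frequencies_hz" in feat:
            feat["frequencies_hz"] = tuple(feat["frequencies_hz"])
        kwargs["features"] = _strict(FeatureSpec, feat, "features")
    if "train" in raw:
        kwargs["train"] = _strict(TrainParams, dict(raw["train"]), "train")
    if "session" in raw:
        kwargs["session"] = _strict(SessionSpec, dict(raw["session"]), "session")
    if "thresholds" in raw:
        kwargs["thresholds"] = _strict(
            NoiseLevelThresholds, dict(raw["thresholds"]), "thresholds"
        )
    return ExperimentConfig(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, complex):
        return [obj.real, obj.imag]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, MotionLabel):
        return obj.name.lower()
    return obj


def config_hash(config: ExperimentConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of a config."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def derive_seed(seed: int, *tags: str | int) -> int:
    """Deterministic child seed (< 2**31) for a named stage of the bench."""
    parts = [int(seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1)[0] % (2**31))
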