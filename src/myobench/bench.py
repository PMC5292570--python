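"""Deterministic synthetic-bench drivers tying the stages together.

Two experiments are emulated end to end on synthetic data:

1. *Electrode comparison* — one sEMG source viewed simultaneously through a
   wet-electrode and a dry PPy-electrode transfer; RMS-envelope Pearson
   correlations over subjects x trials, and band-power comparison around
   150 Hz.
2. *Pattern recognition* — per-condition training of the 24-32-5 network on
   frontend output, then five-task sessions (three 2 s repetitions per
   task, one decision every 10 ms) at the three impedance-imbalance noise
   levels.

Plus the impedance-statistics reproduction (draws vs the reference
level-wise mean/SD), the rest-state noise-level recovery experiment, and
the fixture-table reproduction report.  All randomness descends from one
seed through :func:`myobench.config.derive_seed`.
"""

from __future__ import annotations

import json
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, analysis, fixtures, frontend, pipeline, semg_synth
from .config import ExperimentConfig, config_hash, default_config, derive_seed
from .io import write_signal
from .semg_synth import MotionLabel
from .trace import MeasurementTrace

__all__ = [
    "make_measurement",
    "correlation_experiment",
    "correlation_vs_noise",
    "train_classifier",
    "run_recognition",
    "impedance_experiment",
    "noise_level_recovery",
    "evaluate_fixtures",
    "run_bench",
]

ACTIVE_MOTIONS = tuple(m for m in MotionLabel if m != MotionLabel.RELAX)


def make_measurement(
    cfg: ExperimentConfig,
    motion: MotionLabel,
    condition: str,
    level: int,
    duration_s: float,
    seed: int,
) -> MeasurementTrace:
    """Synthesize one fully processed recording segment.

    source -> electrode transfer (``condition``) -> frontend with an
    impedance state drawn at ``level`` and the default mains interference.
    """
    source = semg_synth.synth_source(
        cfg.source, motion, duration_s, derive_seed(seed, "source", int(motion))
    )
    view = semg_synth.apply_electrode(
        source, cfg.electrodes[condition],
        derive_seed(seed, "electrode", condition, int(motion)),
    )
    state = semg_synth.draw_impedance_state(
        cfg.noise_levels[level], derive_seed(seed, "impedance", level, int(motion))
    )
    return frontend.simulate_measurement(
        view, cfg.interference, state, cfg.amplifier, cfg.filter
    )


def correlation_experiment(
    cfg: ExperimentConfig,
    seed: int,
    n_subjects: int = 4,
    n_trials: int = 3,
) -> list[float]:
    """RMS-envelope correlations between wet and PPy views of one source.

    Each "trial" generates an independent flexion burst, applies both
    electrode transfers with independent measurement noise, and correlates
    the two RMS envelopes.  Returns ``n_subjects * n_trials`` coefficients.
    """
    rs = []
    for s in range(n_subjects):
        for t in range(n_trials):
            trial_seed = derive_seed(seed, "corr", s, t)
            source = semg_synth.synth_source(
                cfg.source, MotionLabel.FLEXION, cfg.session.test_s, trial_seed
            )
            wet = semg_synth.apply_electrode(
                source, cfg.electrodes["wet"], derive_seed(trial_seed, "wet")
            )
            ppy = semg_synth.apply_electrode(
                source, cfg.electrodes["ppy"], derive_seed(trial_seed, "ppy")
            )
            env_w = analysis.rms_envelope(wet)
            env_p = analysis.rms_envelope(ppy)
            rs.append(analysis.pearson_corr(env_w, env_p).r)
    return rs


def correlation_vs_noise(
    cfg: ExperimentConfig,
    seed: int,
    noise_densities: tuple[float, ...] = (2e-6, 2e-5, 1e-4),
    n_trials: int = 4,
) -> list[float]:
    """Mean envelope correlation at increasing independent electrode noise."""
    out = []
    for nd in noise_densities:
        cfg_nd = replace(
            cfg,
            electrodes={
                name: replace(tr, noise_density=nd)
                for name, tr in cfg.electrodes.items()
            },
        )
        rs = correlation_experiment(cfg_nd, derive_seed(seed, "noise", repr(nd)),
                                    n_subjects=1, n_trials=n_trials)
        out.append(float(np.mean(rs)))
    return out


def _training_set(
    cfg: ExperimentConfig, condition: str, level: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    X_parts, y_parts = [], []
    for motion in MotionLabel:
        trace = make_measurement(
            cfg, motion, condition, level, cfg.session.train_s,
            derive_seed(seed, "train", condition, int(motion)),
        )
        X = pipeline.extract_features(trace, cfg.epochs, cfg.features, mode="offline")
        X_parts.append(X)
        y_parts.append(np.full(X.shape[0], int(motion)))
    return np.vstack(X_parts), np.concatenate(y_parts)


def train_classifier(
    cfg: ExperimentConfig,
    condition: str,
    seed: int,
    level: int = 1,
) -> pipeline.AnnModel:
    """Train the 24-32-5 network on per-motion segments at one noise level."""
    X, y = _training_set(cfg, condition, level, seed)
    params = replace(cfg.train, seed=derive_seed(seed, "ann", condition))
    return pipeline.train_ann(X, y, params=params)


def run_recognition(
    cfg: ExperimentConfig,
    model: pipeline.AnnModel,
    condition: str,
    seed: int,
    level: int = 1,
) -> pd.DataFrame:
    """Five-task session at one noise level: per-task accuracy table."""
    segments = []
    for motion in MotionLabel:
        for rep in range(cfg.session.test_reps):
            segments.append(
                (
                    motion,
                    make_measurement(
                        cfg, motion, condition, level, cfg.session.test_s,
                        derive_seed(seed, "test", condition, int(motion), rep),
                    ),
                )
            )
    return pipeline.run_session(segments, model, cfg.epochs, cfg.features,
                                mode="streaming")


def impedance_experiment(
    cfg: ExperimentConfig, seed: int, n_draws: int = 1000
) -> dict[int, analysis.ImbalanceSummary]:
    """Draw impedance states per level and summarize their imbalance indices."""
    out = {}
    for level, spec in sorted(cfg.noise_levels.items()):
        states = semg_synth.draw_impedance_states(
            spec, n_draws, derive_seed(seed, "draws", level)
        )
        mags, phases = zip(*(frontend.imbalance_indices(s) for s in states))
        mag_mean, mag_sd = analysis.summarize(mags)
        ph_mean, ph_sd = analysis.summarize(phases)
        out[level] = analysis.ImbalanceSummary(
            level=level, mag_mean=mag_mean, mag_sd=mag_sd,
            phase_mean=ph_mean, phase_sd=ph_sd, n=n_draws,
        )
    return out


def noise_level_recovery(
    cfg: ExperimentConfig, seed: int, n_repeats: int = 20
) -> pd.DataFrame:
    """Simulate rest recordings per imbalance level and re-classify them.

    For each level: draw an impedance state, run a rest-state (relax)
    measurement through the frontend, classify its noise level from the
    output amplitude, and measure the interference-band power.  Returns one
    row per level with the recovered-level counts and mean harmonic power.
    """
    rows = []
    for level in sorted(cfg.noise_levels):
        recovered = []
        powers = []
        for k in range(n_repeats):
            rep_seed = derive_seed(seed, "recovery", level, k)
            trace = make_measurement(
                cfg, MotionLabel.RELAX, "ppy", level, cfg.session.test_s, rep_seed
            )
            recovered.append(analysis.classify_noise_level(trace, cfg.thresholds))
            powers.append(analysis.harmonic_band_power(trace))
        rows.append(
            {
                "level": level,
                "n": n_repeats,
                "n_recovered": int(sum(r == level for r in recovered)),
                "majority_recovered": sum(r == level for r in recovered) > n_repeats / 2,
                "mean_harmonic_power": float(np.mean(powers)),
            }
        )
    return pd.DataFrame(rows)


def evaluate_fixtures() -> pd.DataFrame:
    """Recompute every summary cell of the packaged tables.

    Returns a tidy report with the computed value, the printed value, the
    printed precision, and whether they agree (the level-1 phase mean is
    compared with a +/-0.1 deg tolerance; see :mod:`myobench.analysis`).
    """
    rows = []

    def add(name, computed, printed, decimals, tol=0.0):
        rounded = analysis.round_half_away(computed, decimals)
        ok = abs(computed - printed) <= tol + 1e-9 if tol else rounded == printed
        rows.append(
            {
                "quantity": name,
                "computed": computed,
                "rounded": rounded,
                "printed": printed,
                "ok": bool(ok),
            }
        )

    t1 = fixtures.load_table1()
    mean, sd = analysis.summarize(t1["r"])
    add("table1_corr_mean", mean, fixtures.PRINTED_TABLE1_SUMMARY["mean"], 2)
    add("table1_corr_sd", sd, fixtures.PRINTED_TABLE1_SUMMARY["sd"], 3)

    t2 = fixtures.load_table2()
    summ = analysis.accuracy_summary(t2)
    for cond in ("wet", "ppy"):
        add(
            f"table2_overall_{cond}",
            float(summ["overall"][cond]),
            fixtures.PRINTED_TABLE2_MEANS["overall"][cond],
            1,
        )
        for task, printed in fixtures.PRINTED_TABLE2_MEANS["per_task"].items():
            # extension/wet averages exactly 83.35 from the printed cells but
            # the table prints 83.3 (rounded from unrounded raw accuracies);
            # compared with a half-ULP tolerance like the level-1 phase mean
            tol = 0.05 if (task, cond) == ("extension", "wet") else 0.0
            add(
                f"table2_{task}_{cond}",
                float(summ["per_task"].loc[task, cond]),
                printed[cond],
                1,
                tol=tol,
            )
        for subj, printed in fixtures.PRINTED_TABLE2_MEANS["per_subject"].items():
            add(
                f"table2_subject{subj}_{cond}",
                float(summ["per_subject"].loc[subj, cond]),
                printed[cond],
                1,
            )

    t3 = fixtures.load_table3()
    for level, printed in fixtures.PRINTED_TABLE3_SUMMARY.items():
        sub = t3[t3["level"] == level]
        mag_mean, mag_sd = analysis.summarize(sub["mag_ohm"])
        ph_mean, ph_sd = analysis.summarize(sub["phase_deg"])
        add(f"table3_l{level}_mag_mean", mag_mean, printed["mag_mean"], 0)
        add(f"table3_l{level}_mag_sd", mag_sd, printed["mag_sd"], 0)
        tol = 0.1 if level == 1 else 0.0
        add(f"table3_l{level}_phase_mean", ph_mean, printed["phase_mean"], 1, tol=tol)
        add(f"table3_l{level}_phase_sd", ph_sd, printed["phase_sd"], 1)
    return pd.DataFrame(rows)


def run_bench(
    cfg: ExperimentConfig | None = None,
    out_dir: str | Path | None = None,
    n_draws: int = 1000,
    n_recovery: int = 20,
) -> dict:
    """Run the full synthetic bench and write a reproducibility report.

    Stages: electrode-correlation experiment, per-condition training and
    three-level recognition sessions, impedance-draw summaries, noise-level
    recovery, and the fixture-table report.  Writes traces, the trained
    models, and ``report.json`` (with seed, config hash and versions) under
    ``out_dir``.  Byte-identical for a fixed seed and config.
    """
    cfg = cfg or default_config()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    report: dict = {
        "manifest": {
            "seed": seed,
            "config_hash": config_hash(cfg),
            "myobench_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
        }
    }

    rs = correlation_experiment(cfg, derive_seed(seed, "correlation"))
    r_mean, r_sd = analysis.summarize(rs)
    report["correlation"] = {"r_values": rs, "mean": r_mean, "sd": r_sd, "n": len(rs)}

    recognition: dict = {}
    for condition in sorted(cfg.electrodes):
        model = train_classifier(cfg, condition, derive_seed(seed, "clf", condition))
        pipeline.save_model(model, out / f"model_{condition}.json")
        recognition[condition] = {}
        for level in sorted(cfg.noise_levels):
            table = run_recognition(
                cfg, model, condition, derive_seed(seed, "session", condition), level
            )
            recognition[condition][str(level)] = table.to_dict(orient="records")
    report["recognition"] = recognition

    report["impedance"] = {
        str(level): vars(s)
        for level, s in impedance_experiment(cfg, derive_seed(seed, "imp"), n_draws).items()
    }
    report["noise_recovery"] = noise_level_recovery(
        cfg, derive_seed(seed, "recov"), n_recovery
    ).to_dict(orient="records")
    report["fixtures"] = evaluate_fixtures().to_dict(orient="records")

    example = make_measurement(
        cfg, MotionLabel.CLOSE, "ppy", 1, cfg.session.test_s, derive_seed(seed, "example")
    )
    write_signal(example, out / "example_close_level1.csv")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
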