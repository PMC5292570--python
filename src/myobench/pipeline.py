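"""Myoelectric pattern recognition: epoching, FFT features, small ANN.

The control pipeline segments each channel into 128 ms epochs advanced every
10 ms, computes the FFT power spectrum per epoch, smooths it with a moving
average, and reads the powers at eight fixed frequencies (31, 55, 78, 102,
148, 195, 258, 320 Hz) per channel — 24 features feeding a 3-layer
feed-forward network (24 input, 32 hidden, 5 output nodes, one per motion
class) trained by backpropagation.

The eight feature frequencies are almost exact multiples of the 128 ms
window's 7.8125 Hz bin spacing (bins 4, 7, 10, 13, 19, 25, 33, 41), which is
asserted at import time for the default configuration.  At a 1600 Hz rate
the window is 205 samples; epochs are zero-padded to a 256-point FFT and
features are read at the nearest FFT bin.

Two epoching conventions are provided: ``offline`` (first full window
onward; a 2 s trace yields 188 epochs) and ``streaming`` (a decision at
every stride boundary using the trailing window, zero pre-roll; 2 s yields
exactly 200 decisions, matching an online controller that classifies every
10 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .semg_synth import MotionLabel
from .trace import MeasurementTrace

__all__ = [
    "EpochConfig",
    "FeatureSpec",
    "FeatureVector",
    "Epoch",
    "AnnModel",
    "TrainParams",
    "epoch_stream",
    "spectral_features",
    "extract_features",
    "init_ann",
    "train_ann",
    "classify_epoch",
    "run_session",
    "dft_bin_offsets",
]

DEFAULT_FEATURE_HZ = (31.0, 55.0, 78.0, 102.0, 148.0, 195.0, 258.0, 320.0)


@dataclass
class EpochConfig:
    """Epoching parameters: 128 ms windows every 10 ms at 1600 Hz."""

    window_ms: float = 128.0
    stride_ms: float = 10.0
    fs: float = 1600.0

    def __post_init__(self) -> None:
        stride = self.stride_ms * self.fs / 1000
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                f"stride of {self.stride_ms} ms is not an integer number of "
                f"samples at {self.fs} Hz"
            )
        if self.window_ms < self.stride_ms:
            raise ValueError("window must be at least one stride long")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.fs / 1000))

    @property
    def stride_samples(self) -> int:
        return int(round(self.stride_ms * self.fs / 1000))

    @property
    def nfft(self) -> int:
        """FFT length: next power of two >= the window length."""
        return 1 << (self.window_samples - 1).bit_length()


@dataclass
class FeatureSpec:
    """Spectral-feature parameters.

    ``smooth_bins`` is the moving-average half-width in FFT bins (window
    ``2*smooth_bins + 1``; default half-width 1, i.e. a 3-bin average).
    """

    frequencies_hz: tuple[float, ...] = DEFAULT_FEATURE_HZ
    smooth_bins: int = 1
    n_channels: int = 3

    def __post_init__(self) -> None:
        if len(self.frequencies_hz) != 8:
            raise ValueError("the feature set uses exactly 8 frequencies")
        if self.smooth_bins < 0:
            raise ValueError("smooth_bins must be >= 0")

    @property
    def n_features(self) -> int:
        return len(self.frequencies_hz) * self.n_channels


@dataclass
class FeatureVector:
    """24 smoothed spectral powers (V^2) for one epoch, channel-major."""

    values: np.ndarray
    epoch_index: int = -1
    label: MotionLabel | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature vector must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("spectral powers must be non-negative")


@dataclass
class Epoch:
    """One analysis window: ``data`` is (n_channels, window_samples)."""

    index: int
    start: int  # sample index of the window start (negative during pre-roll)
    data: np.ndarray
    valid: bool = True


def dft_bin_offsets(
    frequencies_hz: tuple[float, ...] = DEFAULT_FEATURE_HZ,
    window_s: float = 0.128,
) -> np.ndarray:
    """Distance of each feature frequency from its nearest DFT bin (in bins).

    At the 128 ms window's 7.8125 Hz resolution the default frequencies land
    within half a bin of bins {4, 7, 10, 13, 19, 25, 33, 41}.
    """
    pos = np.asarray(frequencies_hz) * window_s
    return pos - np.round(pos)


# The default feature grid must align with the analysis window's bin spacing.
_offsets = dft_bin_offsets()
assert np.all(np.abs(_offsets) <= 0.5), "default feature frequencies misaligned"
assert np.round(np.asarray(DEFAULT_FEATURE_HZ) * 0.128).astype(int).tolist() == [
    4, 7, 10, 13, 19, 25, 33, 41,
]
del _offsets


def epoch_stream(
    trace: MeasurementTrace,
    cfg: EpochConfig,
    mode: str = "offline",
) -> list[Epoch]:
    """Slice a trace into overlapping epochs.

    ``offline``: windows start at sample 0 and advance by one stride; a
    trace of N samples yields ``floor((N - window)/stride) + 1`` epochs.
    ``streaming``: one decision per stride, each using the trailing window
    ending at that stride boundary (zero pre-roll before the trace starts);
    N samples yield ``N // stride`` decisions.

    Epochs whose window overlaps any excluded sample are returned with
    ``valid=False`` and must be skipped by analysis.
    """
    if abs(cfg.fs - trace.fs) > 1e-9:
        raise ValueError(f"epoch config fs {cfg.fs} != trace fs {trace.fs}")
    win, stride = cfg.window_samples, cfg.stride_samples
    n = trace.n_samples
    if mode == "offline":
        if n < win:
            raise ValueError("trace shorter than one analysis window")
        starts = range(0, n - win + 1, stride)
    elif mode == "streaming":
        if n < stride:
            raise ValueError("trace shorter than one stride")
        starts = range(stride - win, n - win + 1, stride)
    else:
        raise ValueError(f"unknown epoching mode {mode!r}")

    epochs = []
    for i, s in enumerate(starts):
        if s < 0:
            data = np.concatenate(
                [np.zeros((trace.n_channels, -s)), trace.samples[:, : s + win]], axis=1
            )
            tainted = bool(trace.excluded_mask[: s + win].any())
        else:
            data = trace.samples[:, s : s + win]
            tainted = bool(trace.excluded_mask[s : s + win].any())
        epochs.append(Epoch(index=i, start=s, data=data, valid=not tainted))
    return epochs


def spectral_features(
    epoch: Epoch | np.ndarray,
    spec: FeatureSpec,
    cfg: EpochConfig,
) -> FeatureVector:
    """Smoothed FFT powers at the eight feature frequencies per channel.

    Per channel: zero-pad the window to ``cfg.nfft``, take the magnitude-
    squared spectrum (normalized by the window length), smooth with a
    centered ``2*smooth_bins + 1`` moving average, and read the power at the
    FFT bin nearest each feature frequency.  Values are concatenated
    channel-major (channel 1's eight powers first).
    """
    data = epoch.data if isinstance(epoch, Epoch) else np.atleast_2d(epoch)
    if data.shape[1] != cfg.window_samples:
        raise ValueError(
            f"epoch length {data.shape[1]} != window {cfg.window_samples}"
        )
    if data.shape[0] != spec.n_channels:
        raise ValueError(f"expected {spec.n_channels} channels, got {data.shape[0]}")
    nfft = cfg.nfft
    if any(f >= cfg.fs / 2 for f in spec.frequencies_hz):
        raise ValueError("feature frequencies must lie below Nyquist")

    power = np.abs(np.fft.rfft(data, n=nfft, axis=1)) ** 2 / cfg.window_samples
    if spec.smooth_bins > 0:
        w = 2 * spec.smooth_bins + 1
        kernel = np.ones(w) / w
        power = np.apply_along_axis(
            lambda p: np.convolve(p, kernel, mode="same"), 1, power
        )
    bins = [int(round(f * nfft / cfg.fs)) for f in spec.frequencies_hz]
    values = power[:, bins].reshape(-1)
    idx = epoch.index if isinstance(epoch, Epoch) else -1
    return FeatureVector(values=values, epoch_index=idx)


def extract_features(
    trace: MeasurementTrace,
    cfg: EpochConfig,
    spec: FeatureSpec,
    mode: str = "offline",
) -> np.ndarray:
    """Feature matrix (n_valid_epochs x n_features) for one trace."""
    rows = [
        spectral_features(ep, spec, cfg).values
        for ep in epoch_stream(trace, cfg, mode=mode)
        if ep.valid
    ]
    if not rows:
        raise ValueError("no valid epochs in trace")
    return np.vstack(rows)


@dataclass
class TrainParams:
    """Backpropagation hyperparameters (package defaults, freely tunable)."""

    learning_rate: float = 0.1
    epochs: int = 600
    seed: int = 0
    init_scale: float = 0.5  # uniform(-scale, scale) weight init


@dataclass
class AnnModel:
    """3-layer feed-forward network with logistic-sigmoid activations.

    Inputs are z-scored with statistics stored in the model (``x_mean``,
    ``x_std``), learned from the training set.  Output nodes are one-hot
    motion-class targets; classification takes the argmax (ties break to the
    lowest class index).
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    activation: str = "logistic"
    train_params: TrainParams = field(default_factory=TrainParams)
    trained: bool = False
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w1.shape[0], self.w1.shape[1], self.w2.shape[1])

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Network outputs for inputs of shape (n, n_in) or (n_in,)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.x_mean) / self.x_std
        h = _sigmoid(z @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1 / (1 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1 + ex)
    return out


def init_ann(
    n_inputs: int = 24,
    n_hidden: int = 32,
    n_outputs: int = 5,
    seed: int = 0,
    init_scale: float = 0.5,
) -> AnnModel:
    """Seeded uniform(-init_scale, init_scale) weight initialization."""
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(-init_scale, init_scale, shape)
    return AnnModel(
        w1=u(n_inputs, n_hidden),
        b1=u(n_hidden),
        w2=u(n_hidden, n_outputs),
        b2=u(n_outputs),
        x_mean=np.zeros(n_inputs),
        x_std=np.ones(n_inputs),
    )


def train_ann(
    features: np.ndarray,
    labels: np.ndarray,
    model_init: AnnModel | None = None,
    params: TrainParams | None = None,
) -> AnnModel:
    """Train the network with full-batch backpropagation (MSE loss).

    Every motion class must be represented at least once.  Each epoch takes
    one gradient step with a halving line search, so the recorded training
    loss is non-increasing; a NaN loss aborts with a diagnostic.
    Deterministic given ``params.seed``.
    """
    params = params or TrainParams()
    X = np.asarray(features, dtype=float)
    y = np.asarray([int(l) for l in labels])
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have matching first dimension")
    missing = [m for m in MotionLabel if int(m) not in set(y.tolist())]
    if missing:
        raise ValueError(f"missing training examples for classes {missing}")

    n_out = len(MotionLabel)
    model = model_init or init_ann(
        n_inputs=X.shape[1], n_outputs=n_out, seed=params.seed,
        init_scale=params.init_scale,
    )
    model.x_mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    model.x_std = std
    Xz = (X - model.x_mean) / model.x_std
    T = np.eye(n_out)[y]

    def loss_and_grads(w1, b1, w2, b2):
        h = _sigmoid(Xz @ w1 + b1)
        o = _sigmoid(h @ w2 + b2)
        err = o - T
        loss = float(np.mean(err**2))
        n = Xz.shape[0]
        d_o = 2 * err * o * (1 - o) / (n * n_out)
        gw2 = h.T @ d_o
        gb2 = d_o.sum(axis=0)
        d_h = (d_o @ w2.T) * h * (1 - h)
        gw1 = Xz.T @ d_h
        gb1 = d_h.sum(axis=0)
        return loss, (gw1, gb1, gw2, gb2)

    w = [model.w1.copy(), model.b1.copy(), model.w2.copy(), model.b2.copy()]
    lr = params.learning_rate
    history = np.empty(params.epochs + 1)
    loss, grads = loss_and_grads(*w)
    history[0] = loss
    for epoch in range(params.epochs):
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged (loss={loss}) at epoch {epoch}; "
                "reduce the learning rate"
            )
        step = lr
        for _ in range(40):
            trial = [wi - step * gi for wi, gi in zip(w, grads)]
            new_loss, new_grads = loss_and_grads(*trial)
            if new_loss <= loss:
                break
            step /= 2
        else:  # flat to machine precision: keep current weights
            trial, new_loss, new_grads = w, loss, grads
        w, loss, grads = trial, new_loss, new_grads
        # the halving search makes larger trial steps safe, so the step is
        # allowed to grow well beyond the configured base rate
        lr = min(step * 1.5, 1e4 * params.learning_rate)
        history[epoch + 1] = loss

    model.w1, model.b1, model.w2, model.b2 = w
    model.train_params = params
    model.trained = True
    model.loss_history = history
    return model


def classify_epoch(model: AnnModel, fv: FeatureVector | np.ndarray) -> MotionLabel:
    """Argmax over the output layer; ties break to the lowest class index."""
    if not model.trained:
        raise ValueError("model has not been trained")
    values = fv.values if isinstance(fv, FeatureVector) else np.asarray(fv)
    out = model.forward(values)[0]
    return MotionLabel(int(np.argmax(out)))


def save_model(model: AnnModel, path) -> None:
    """Dump trained weights to a portable plain-text JSON file."""
    import json

    blob = {
        "format_version": 1,
        "layer_sizes": list(model.layer_sizes),
        "activation": model.activation,
        "trained": model.trained,
        "seed": model.train_params.seed,
        "train_params": {
            "learning_rate": model.train_params.learning_rate,
            "epochs": model.train_params.epochs,
            "seed": model.train_params.seed,
            "init_scale": model.train_params.init_scale,
        },
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_model(path) -> AnnModel:
    """Load a model written by :func:`save_model`."""
    import json

    with open(path) as fh:
        blob = json.load(fh)
    if blob.get("format_version") != 1:
        raise ValueError(f"unsupported model format version {blob.get('format_version')}")
    model = AnnModel(
        w1=np.asarray(blob["w1"]),
        b1=np.asarray(blob["b1"]),
        w2=np.asarray(blob["w2"]),
        b2=np.asarray(blob["b2"]),
        x_mean=np.asarray(blob["x_mean"]),
        x_std=np.asarray(blob["x_std"]),
        activation=blob["activation"],
        train_params=TrainParams(**blob["train_params"]),
        trained=bool(blob["trained"]),
    )
    return model


def run_session(
    segments: list[tuple[MotionLabel, MeasurementTrace]],
    model: AnnModel,
    cfg: EpochConfig,
    spec: FeatureSpec,
    mode: str = "streaming",
) -> pd.DataFrame:
    """Classify per-task segments and tabulate per-task accuracy.

    ``segments`` holds one or more recordings per task (e.g. three 2 s
    repetitions).  Returns a table with one row per task plus a ``mean``
    row; accuracy is percent of correct decisions over all decisions for
    that task.  Excluded (masked) epochs are skipped.
    """
    if not segments:
        raise ValueError("no segments supplied")
    counts: dict[MotionLabel, list[int]] = {}
    for label, trace in segments:
        if trace.n_samples == 0:
            raise ValueError("empty segment")
        correct = total = 0
        for ep in epoch_stream(trace, cfg, mode=mode):
            if not ep.valid:
                continue
            fv = spectral_features(ep, spec, cfg)
            pred = classify_epoch(model, fv)
            total += 1
            correct += int(pred == label)
        c = counts.setdefault(label, [0, 0])
        c[0] += correct
        c[1] += total
    rows = []
    for label in sorted(counts, key=int):
        correct, total = counts[label]
        rows.append(
            {
                "task": label.name.lower(),
                "n_decisions": total,
                "n_correct": correct,
                "accuracy_pct": 100.0 * correct / total if total else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    mean_row = {
        "task": "mean",
        "n_decisions": int(table["n_decisions"].sum()),
        "n_correct": int(table["n_correct"].sum()),
        "accuracy_pct": float(table["accuracy_pct"].mean()),
    }
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
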