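"""Sleep-stage sequence classifier: raw 30-s EEG windows → stage probabilities.

A compact convolutional–recurrent classifier in the canonical shape for
automatic sleep scoring: a stack of 1-D convolution + max-pooling blocks
extracts spectral/temporal features from a z-scored 30-s window, a
bidirectional LSTM integrates them over the window, and a dense softmax
head emits the 5 stage probabilities.  The full-size reference layout is
eleven convolutions, nine pooling layers and two bidirectional LSTMs; a
``scale_factor`` shrinks depth and width proportionally for desk-scale
experiments (the default tests train a small instance on the synthetic
stage-signatured EEG from :mod:`hypnocycle.synth`).

The network is implemented on the plain-numpy layers of
:mod:`hypnocycle.nn` and trained with backpropagation (Adam, cross-entropy).
Sliding a 30-s window at a 5-s step over a recording and collecting the
softmax outputs at the window centers yields a
:class:`~hypnocycle.core.HypnodensitySeries`; tapping intermediate layers
yields the labeled embeddings that :mod:`hypnocycle.gdv` profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Hypnogram,
    HypnodensitySeries,
    sliding_window_times,
    train_test_split_datasets,
)
from .gdv import LabeledEmbedding
from .nn import Adam, BiLSTM, Conv1D, Dense, MaxPool1D, ReLU, softmax, softmax_cross_entropy

#: Number of pooling layers tapped for embedding profiles (plus input,
#: final LSTM and softmax).
_N_POOL_TAPS = 6


@dataclass
class NetworkSpec:
    """Architecture description.

    At full scale (``scale_factor=1``) the layer census is 11 convolutional
    layers, 9 max-pooling layers and 2 bidirectional LSTM layers ahead of
    the 5-way softmax head.  ``scale_factor`` < 1 shrinks both depth and
    width (at least one of each layer type always remains).
    """

    n_conv_layers: int = 11
    n_pool_layers: int = 9
    n_lstm_layers: int = 2
    n_classes: int = 5
    scale_factor: float = 1.0
    pool_size: int = 2
    conv_channels: int = 16
    lstm_hidden: int = 32

    def __post_init__(self):
        if self.n_classes != 5:
            raise ValueError("the sleep-stage classifier is defined for 5 classes")
        if min(self.n_conv_layers, self.n_pool_layers, self.n_lstm_layers) <= 0:
            raise ValueError("layer counts must be positive")
        if not 0 < self.scale_factor <= 1:
            raise ValueError("scale_factor must lie in (0, 1]")

    def effective_counts(self) -> dict[str, int]:
        f = self.scale_factor
        return {
            "conv": max(1, round(self.n_conv_layers * f)),
            "pool": max(1, round(self.n_pool_layers * f)),
            "lstm": max(1, round(self.n_lstm_layers * f)),
            "channels": max(4, round(self.conv_channels * f)),
            "hidden": max(8, round(self.lstm_hidden * f)),
        }


class SleepStageClassifier:
    """Trainable conv + biLSTM sleep-stage classifier (see module docstring)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        eff = spec.effective_counts()
        rng = np.random.default_rng(seed)
        self.conv_stack = []
        self.pool_positions: list[int] = []  # indices into conv_stack after assembly
        c_in = 1
        pools_placed = 0
        n_conv, n_pool = eff["conv"], eff["pool"]
        for i in range(n_conv):
            kernel = 7 if i == 0 else 3
            self.conv_stack.append(Conv1D(c_in, eff["channels"], kernel, rng))
            self.conv_stack.append(ReLU())
            c_in = eff["channels"]
            # distribute the pools evenly across the conv layers
            due = ((i + 1) * n_pool) // n_conv
            while pools_placed < due:
                self.conv_stack.append(MaxPool1D(spec.pool_size))
                self.pool_positions.append(len(self.conv_stack) - 1)
                pools_placed += 1
        self.lstm_stack = []
        f_in = c_in
        for j in range(eff["lstm"]):
            last = j == eff["lstm"] - 1
            self.lstm_stack.append(
                BiLSTM(f_in, eff["hidden"], rng, return_sequences=not last)
            )
            f_in = 2 * eff["hidden"]
        self.head = Dense(f_in, spec.n_classes, rng)
        self._layers = self.conv_stack + self.lstm_stack + [self.head]

    # -- structure ---------------------------------------------------------

    def layer_census(self) -> dict[str, int]:
        """Counts of each layer type actually built."""
        return {
            "conv": sum(isinstance(l, Conv1D) for l in self.conv_stack),
            "pool": sum(isinstance(l, MaxPool1D) for l in self.conv_stack),
            "lstm": len(self.lstm_stack),
            "dense": 1,
        }

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def _preprocess(windows: np.ndarray) -> np.ndarray:
        """Z-score each window (the network input representation)."""
        w = np.asarray(windows, dtype=float)
        if w.ndim != 2:
            raise ValueError("windows must be a (n_windows, n_samples) matrix")
        mu = w.mean(axis=1, keepdims=True)
        sd = w.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (w - mu) / sd

    def _forward(self, windows: np.ndarray, taps: dict | None = None) -> np.ndarray:
        z = self._preprocess(windows)
        if taps is not None:
            taps["input"] = z.copy()
        x = z[:, None, :]  # (B, 1, L)
        pool_no = 0
        for i, layer in enumerate(self.conv_stack):
            x = layer.forward(x)
            if taps is not None and isinstance(layer, MaxPool1D):
                pool_no += 1
                taps[f"pool{pool_no}"] = x.reshape(x.shape[0], -1).copy()
        h = np.transpose(x, (0, 2, 1))  # (B, T, F)
        if h.shape[1] < 1:
            raise ValueError("input too short for this network depth")
        for layer in self.lstm_stack:
            h = layer.forward(h)
        if taps is not None:
            taps["lstm"] = h.copy()
        logits = self.head.forward(h)
        if taps is not None:
            taps["softmax"] = softmax(logits)
        return logits

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        for layer in reversed(self.lstm_stack):
            d = layer.backward(d)
        d = np.transpose(d, (0, 2, 1))
        for layer in reversed(self.conv_stack):
            d = layer.backward(d)

    # -- public API --------------------------------------------------------

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Stage probabilities, one simplex row per 30-s window."""
        windows = np.asarray(windows, dtype=float)
        out = [
            softmax(self._forward(windows[i : i + batch_size]))
            for i in range(0, windows.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def fit(
        self,
        windows: np.ndarray,
        labels: np.ndarray,
        epochs: int = 15,
        batch_size: int = 64,
        lr: float = 1e-3,
        seed: int = 0,
        verbose: bool = False,
    ) -> list[float]:
        """Train with Adam on cross-entropy; returns the per-epoch mean loss."""
        windows = np.asarray(windows, dtype=float)
        labels = np.asarray(labels, dtype=np.intp)
        if windows.shape[0] != labels.shape[0]:
            raise ValueError("windows and labels must have equal length")
        rng = np.random.default_rng(seed)
        opt = Adam(self._layers, lr=lr)
        history = []
        n = windows.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self._forward(windows[idx])
                loss, dlogits = softmax_cross_entropy(logits, labels[idx])
                self._backward(dlogits)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if verbose:  # pragma: no cover - logging convenience
                print(f"epoch {epoch + 1}/{epochs}  loss {history[-1]:.4f}")
        return history

    def accuracy(self, windows: np.ndarray, labels: np.ndarray) -> float:
        pred = np.argmax(self.predict_proba(windows), axis=1)
        return float(np.mean(pred == np.asarray(labels)))


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> SleepStageClassifier:
    """Construct a (trainable) classifier from an architecture spec."""
    return SleepStageClassifier(spec or NetworkSpec(), seed=seed)


def extract_windows(
    signal: np.ndarray,
    sample_rate: float,
    window_seconds: float = 30.0,
    step_seconds: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a 1-D signal into fully contained windows.

    Returns ``(windows, center_times)``; ``step_seconds`` defaults to the
    window length (non-overlapping epochs).
    """
    signal = np.asarray(signal, dtype=float)
    step = window_seconds if step_seconds is None else step_seconds
    record = signal.size / sample_rate
    centers = sliding_window_times(record, window_seconds, step)
    n_win = int(round(window_seconds * sample_rate))
    n_step = step * sample_rate
    starts = np.round(np.arange(centers.size) * n_step).astype(int)
    windows = np.stack([signal[s : s + n_win] for s in starts]) if centers.size else \
        np.empty((0, n_win))
    return windows, centers


def prepare_training_data(
    datasets: list[tuple],
    sample_rate: float,
    train_fraction: float = 0.8,
    seed: int | None = None,
):
    """Windowed train/test corpora from (signals, hypnogram) datasets.

    Each dataset is ``(signal | list of per-channel signals, Hypnogram)``.
    Multi-channel recordings are concatenated channel-wise into one stream
    (three channels → one stream of three times the duration) before
    windowing into non-overlapping 30-s epochs labeled from the hypnogram;
    artifact epochs are excluded.  The split is at dataset level via
    :func:`~hypnocycle.core.train_test_split_datasets`.

    Returns ``(x_train, y_train, x_test, y_test)``.
    """
    train_idx, test_idx = train_test_split_datasets(len(datasets), train_fraction, seed)

    def _collect(indices):
        xs, ys = [], []
        for i in indices:
            signals, hyp = datasets[i]
            channel_list = signals if isinstance(signals, (list, tuple)) else [signals]
            for sig in channel_list:
                sig = np.asarray(sig, dtype=float)
                if sig.size != round(hyp.duration_seconds * sample_rate):
                    raise ValueError(
                        f"dataset {i}: signal length does not match the hypnogram duration"
                    )
                windows, _ = extract_windows(sig, sample_rate, hyp.epoch_seconds)
                n = min(windows.shape[0], hyp.n_epochs)
                keep = ~hyp.artifact_mask[:n]
                xs.append(windows[:n][keep])
                ys.append(hyp.stages[:n][keep])
        return np.concatenate(xs), np.concatenate(ys)

    x_train, y_train = _collect(train_idx)
    x_test, y_test = _collect(test_idx)
    return x_train, y_train, x_test, y_test


def predict_hypnodensity(
    model: SleepStageClassifier,
    signal: np.ndarray,
    sample_rate: float,
    step_seconds: float = 5.0,
    window_seconds: float = 30.0,
    channel: str = "",
) -> HypnodensitySeries:
    """Sliding-window softmax output of the classifier as a hypnodensity.

    A 30-s window slides at ``step_seconds``; each probability vector is
    assigned to its window center.  The signal must cover at least one
    window.
    """
    windows, centers = extract_windows(signal, sample_rate, window_seconds, step_seconds)
    if windows.shape[0] == 0:
        raise ValueError("signal shorter than one analysis window")
    probs = model.predict_proba(windows)
    return HypnodensitySeries(
        times=centers, probs=probs, channel=channel,
        step_seconds=step_seconds, window_seconds=window_seconds,
    )


def tap_layer_embeddings(
    model: SleepStageClassifier,
    windows: np.ndarray,
    labels: np.ndarray,
    layers: list[str] | None = None,
) -> list[LabeledEmbedding]:
    """Labeled embeddings of the same windows at successive network layers.

    By default taps the input, up to six evenly spaced pooling layers, the
    final LSTM output and the softmax output — the standard set for a
    layer-wise separability (GDV) profile.  Pass explicit tap names (e.g.
    ``["input", "pool2", "softmax"]``) to override.
    """
    labels = np.asarray(labels)
    taps: dict[str, np.ndarray] = {}
    model._forward(np.asarray(windows, dtype=float), taps=taps)
    pool_names = [k for k in taps if k.startswith("pool")]
    if layers is None:
        if len(pool_names) > _N_POOL_TAPS:
            sel = np.linspace(0, len(pool_names) - 1, _N_POOL_TAPS).round().astype(int)
            pool_names = [pool_names[i] for i in sorted(set(sel))]
        layers = ["input"] + pool_names + ["lstm", "softmax"]
    unknown = [name for name in layers if name not in taps]
    if unknown:
        raise ValueError(f"unknown layer name(s): {unknown}; available: {sorted(taps)}")
    return [
        LabeledEmbedding(points=taps[name], labels=labels, layer_name=name)
        for name in layers
    ]
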