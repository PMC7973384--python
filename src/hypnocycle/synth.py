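"""Synthetic sleep data: cyclic hypnograms, softmax-like hypnodensities,
multi-channel variants, labeled Gaussian clusters and toy stage-signatured EEG.

The generators give every analysis in the package a self-contained,
download-free input.  The sleep model is deliberately simple: a night is a
succession of ultradian cycles, each running through the stage template
N1 → N2 → N3 → N2 → REM.  The cycle clock is stable — every cycle's total
length equals the nominal period (rounded to whole 30-s epochs) — while
``dwell_jitter`` randomizes how the stages share each cycle and
``wake_insertion_rate`` sprinkles brief awakenings.  Probability noise
emulates classifier softmax uncertainty: each frame draws a Dirichlet
vector concentrated on the true stage, blended with a stage-confusion
kernel and optional per-channel stage biases.  None of this models real
sleep microstructure (arousals, stage-transition asymmetries, first-cycle
N3 dominance); it models exactly the periodic structure and simplex noise
the correlation and separability analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    N_STAGES,
    Hypnogram,
    HypnodensitySeries,
    hypnogram_to_hypnodensity,
)
from .gdv import LabeledEmbedding

#: Stage indices of the default within-cycle template (N1 N2 N3 N2 REM).
DEFAULT_TEMPLATE_STAGES = (1, 2, 3, 2, 4)
#: Fraction of the cycle each template segment occupies.
DEFAULT_TEMPLATE_FRACTIONS = (0.10, 0.40, 0.25, 0.10, 0.15)

#: Mild channel-specific stage biases emulating electrode-position effects:
#: a central channel slightly over-reporting Wake and an occipital channel
#: slightly over-reporting deep sleep.
DEFAULT_CHANNEL_BIAS: dict[str, tuple[float, ...]] = {
    "C4": (1.3, 1.0, 1.0, 1.0, 1.0),
    "F4": (1.0, 1.0, 1.0, 1.0, 1.0),
    "O2": (1.0, 1.0, 1.0, 1.3, 1.0),
}

_DEFAULT_CONFUSION = np.array(
    [
        # reported:  W     N1    N2    N3    REM      true stage:
        [0.850, 0.090, 0.030, 0.010, 0.020],  # Wake
        [0.050, 0.850, 0.050, 0.010, 0.040],  # N1
        [0.010, 0.050, 0.850, 0.060, 0.030],  # N2
        [0.005, 0.005, 0.130, 0.850, 0.010],  # N3
        [0.020, 0.060, 0.030, 0.010, 0.880],  # REM
    ]
)


@dataclass
class CyclicSleepModel:
    """Generative parameters for a cyclic synthetic night.

    ``cycle_period`` is the ultradian period in seconds (healthy adults:
    ~75–110 min).  ``dwell_jitter`` is the log-normal sigma applied
    multiplicatively to the per-stage dwell fractions within each cycle
    (cycle totals stay fixed); ``wake_insertion_rate`` is the expected
    number of brief (1-epoch) awakenings per hour.
    """

    cycle_period: float = 90 * 60.0
    total_duration: float = 8 * 3600.0
    epoch_seconds: float = 30.0
    stage_template: tuple[int, ...] = DEFAULT_TEMPLATE_STAGES
    dwell_fractions: tuple[float, ...] = DEFAULT_TEMPLATE_FRACTIONS
    wake_insertion_rate: float = 1.0
    dwell_jitter: float = 0.05

    def __post_init__(self):
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if len(self.stage_template) != len(self.dwell_fractions):
            raise ValueError("stage_template and dwell_fractions lengths differ")
        fr = np.asarray(self.dwell_fractions, dtype=float)
        if np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("dwell fractions must be positive and sum to 1")
        if any(not 0 <= s < N_STAGES for s in self.stage_template):
            raise ValueError("stage template indices must lie in 0..4")
        if self.dwell_jitter < 0 or self.wake_insertion_rate < 0:
            raise ValueError("jitter and wake rate must be non-negative")


@dataclass
class NoiseModel:
    """Softmax-style probability noise around the true stage.

    ``concentration`` scales the Dirichlet parameters (larger → sharper,
    infinity → one-hot).  ``confusion_kernel`` rows give, per true stage,
    the target probability mass over reported stages (adjacent stages such
    as N2/N3 receive most of the off-diagonal mass).  ``channel_bias`` maps
    channel labels to 5 multiplicative stage weights applied before
    renormalization.
    """

    concentration: float = 40.0
    confusion_kernel: np.ndarray = field(default_factory=lambda: _DEFAULT_CONFUSION.copy())
    channel_bias: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        self.confusion_kernel = np.asarray(self.confusion_kernel, dtype=float)
        if self.confusion_kernel.shape != (N_STAGES, N_STAGES):
            raise ValueError("confusion_kernel must be 5 x 5")
        if np.any(self.confusion_kernel < 0):
            raise ValueError("confusion_kernel weights must be non-negative")
        row_sums = self.confusion_kernel.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ValueError("confusion_kernel has an all-zero row")
        self.confusion_kernel = self.confusion_kernel / row_sums[:, None]

    def bias_for(self, channel: str) -> np.ndarray:
        w = np.asarray(self.channel_bias.get(channel, np.ones(N_STAGES)), dtype=float)
        if w.shape != (N_STAGES,) or np.any(w <= 0):
            raise ValueError(f"channel bias for {channel!r} must be 5 positive weights")
        return w


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` across fractions, each share >= 1."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    base = np.maximum(base, 1)
    excess = base.sum() - total
    if excess > 0:  # shrink the largest shares
        order = np.argsort(-base)
        for i in order:
            take = min(excess, base[i] - 1)
            base[i] -= take
            excess -= take
            if excess == 0:
                break
    elif excess < 0:  # distribute by largest remainder
        rema = raw - np.floor(raw)
        order = np.argsort(-rema)
        for i in order[: -excess]:
            base[i] += 1
    return base


def simulate_hypnogram(model: CyclicSleepModel, seed: int | None = None) -> Hypnogram:
    """Simulate a cyclic full-night hypnogram at 30-s epochs.

    Each cycle realizes the stage template; ``dwell_jitter`` perturbs the
    dwell fractions log-normally, then the dwells are rescaled so every
    cycle occupies exactly ``round(cycle_period / epoch_seconds)`` epochs
    (a stable ultradian clock).  Brief 1-epoch awakenings are inserted as a
    Poisson process at ``wake_insertion_rate`` per hour.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_total = int(round(model.total_duration / model.epoch_seconds))
    per_cycle = int(round(model.cycle_period / model.epoch_seconds))
    if per_cycle < len(model.stage_template):
        raise ValueError("cycle_period too short for the stage template")
    if n_total < per_cycle:
        raise ValueError("total_duration must cover at least one full cycle")

    fractions = np.asarray(model.dwell_fractions, dtype=float)
    template = np.asarray(model.stage_template, dtype=np.intp)
    epochs: list[np.ndarray] = []
    n_done = 0
    while n_done < n_total:
        if model.dwell_jitter > 0:
            f = fractions * np.exp(rng.normal(0.0, model.dwell_jitter, fractions.size))
            f = f / f.sum()
        else:
            f = fractions
        dwells = _largest_remainder(f, per_cycle)
        cycle = np.repeat(template, dwells)
        epochs.append(cycle[: n_total - n_done])
        n_done += epochs[-1].size
    stages = np.concatenate(epochs)

    hours = n_total * model.epoch_seconds / 3600.0
    n_wake = rng.poisson(model.wake_insertion_rate * hours)
    if n_wake > 0:
        where = rng.integers(0, n_total, size=n_wake)
        stages[where] = 0
    return Hypnogram(stages=stages, epoch_seconds=model.epoch_seconds)


def simulate_noisy_hypnodensity(
    h: Hypnogram,
    noise: NoiseModel | None = None,
    step_seconds: float = 5.0,
    channel: str = "",
    seed: int | None = None,
) -> HypnodensitySeries:
    """Softmax-like noisy hypnodensity of a hypnogram.

    Per frame the target simplex vector is the true stage's confusion-kernel
    row, multiplied by the channel bias and renormalized; the emitted row is
    a Dirichlet draw with parameters ``concentration * target`` (plus a tiny
    floor so all parameters are positive).  Rows therefore live exactly on
    the simplex and the argmax matches the true stage in the vast majority
    of frames at the default concentration.
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    truth = hypnogram_to_hypnodensity(h, step_seconds=step_seconds, channel=channel)
    true_stage = np.argmax(truth.probs, axis=1)
    bias = noise.bias_for(channel)
    targets = noise.confusion_kernel[true_stage] * bias
    targets = targets / targets.sum(axis=1, keepdims=True)
    alphas = noise.concentration * targets + 1e-3
    draws = rng.standard_gamma(alphas)
    probs = draws / draws.sum(axis=1, keepdims=True)
    return HypnodensitySeries(
        times=truth.times, probs=probs, channel=channel,
        step_seconds=step_seconds, window_seconds=truth.window_seconds,
    )


def simulate_multichannel(
    h: Hypnogram,
    noise: NoiseModel | None = None,
    channels: tuple[str, ...] = ("C4", "F4", "O2"),
    step_seconds: float = 5.0,
    seed: int | None = None,
) -> list[HypnodensitySeries]:
    """Multi-channel hypnodensities sharing one hypnogram.

    Channels share the underlying stage sequence (a common generative
    clock, so any cross-correlation peaks at lag 0) but draw independent
    probability noise and apply their per-channel biases.  Keys of
    ``noise.channel_bias`` must name requested channels.
    """
    if len(channels) < 1:
        raise ValueError("need at least one channel")
    noise = noise if noise is not None else NoiseModel()
    unknown = set(noise.channel_bias) - set(channels)
    if unknown:
        raise ValueError(f"channel_bias keys not among requested channels: {sorted(unknown)}")
    children = np.random.SeedSequence(seed).spawn(len(channels))
    return [
        simulate_noisy_hypnodensity(
            h, noise=noise, step_seconds=step_seconds, channel=ch,
            seed=np.random.default_rng(child).integers(2**31),
        )
        for ch, child in zip(channels, children)
    ]


def simulate_embeddings(
    n_classes: int = 2,
    n_per_class: int = 100,
    dim: int = 10,
    separation: float = 0.0,
    cluster_std: float = 1.0,
    seed: int | None = None,
) -> LabeledEmbedding:
    """Isotropic Gaussian class clusters with controllable separation.

    Class centroids sit at the vertices of a regular simplex scaled so that
    every pair of centroids is exactly ``separation`` apart (requires
    ``dim >= n_classes``); points are drawn N(centroid, cluster_std² I).
    ``separation=0`` collapses all classes onto one distribution.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if dim < n_classes:
        raise ValueError("dim must be >= n_classes for the simplex construction")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    centroids = np.zeros((n_classes, dim))
    centroids[:, :n_classes] = (separation / np.sqrt(2.0)) * np.eye(n_classes)
    points = np.concatenate(
        [c + cluster_std * rng.standard_normal((n_per_class, dim)) for c in centroids]
    )
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return LabeledEmbedding(points=points, labels=labels, layer_name="synthetic")


#: Per-stage oscillation recipes for the toy EEG: (frequency Hz, amplitude).
_STAGE_TONES: dict[int, list[tuple[float, float]]] = {
    0: [(10.0, 1.0)],               # Wake: alpha
    1: [(5.0, 0.8)],                # N1: slow theta
    2: [(13.0, 1.0), (2.0, 0.3)],   # N2: spindle band (burst-modulated) + slow
    3: [(1.5, 2.0)],                # N3: high-amplitude delta
    4: [(7.5, 0.7), (20.0, 0.4)],   # REM: theta + low beta
}
_NOISE_AMP = 0.4


def simulate_stage_eeg(
    h: Hypnogram, sample_rate: float = 64.0, seed: int | None = None
) -> np.ndarray:
    """Toy single-channel EEG with standard per-stage spectral signatures.

    Each epoch gets broadband noise plus stage-specific oscillations with a
    random phase: alpha (~10 Hz) for Wake, slow high-amplitude delta for N3,
    burst-modulated spindle-band activity for N2, theta-range activity for
    N1/REM.  Epochs are amplitude-normalized (zero mean, unit variance).
    Purely a test signal: no 1/f background, no K-complexes, no artifacts.
    """
    if sample_rate < 64:
        raise ValueError("sample_rate must be at least 64 Hz")
    rng = np.random.default_rng(seed)
    n_ep = int(round(h.epoch_seconds * sample_rate))
    t = np.arange(n_ep) / sample_rate
    out = np.empty(h.n_epochs * n_ep)
    for i, stage in enumerate(h.stages):
        sig = _NOISE_AMP * rng.standard_normal(n_ep)
        for freq, amp in _STAGE_TONES[int(stage)]:
            phase = rng.uniform(0, 2 * np.pi)
            tone = amp * np.sin(2 * np.pi * freq * t + phase)
            if stage == 2 and freq > 10:  # spindles come in ~1 s bursts every 3 s
                envelope = (np.sin(2 * np.pi * t / 3.0) > 0.5).astype(float)
                tone = tone * envelope
            sig += tone
        sig -= sig.mean()
        sig /= sig.std()
        out[i * n_ep : (i + 1) * n_ep] = sig
    return out
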