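"""Domain types for sleep staging: hypnograms and hypnodensity series.

A *hypnogram* is the classic per-epoch sequence of discrete sleep stages
(30-s epochs by AASM convention).  A *hypnodensity series* generalizes it to
a time series of full probability distributions over the five stages
(Wake, N1, N2, N3, REM) — the softmax output of an automatic scorer, or the
degenerate one-hot embedding of a hypnogram.  All downstream analyses
(vectorial correlations, plots) operate on hypnodensity series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: Canonical stage order used for every file, array and plot in the package.
STAGE_LABELS = ("Wake", "N1", "N2", "N3", "REM")
#: Short labels used in hypnogram text files.
STAGE_SHORT = ("W", "N1", "N2", "N3", "REM")
N_STAGES = 5

#: Tolerance on probability-row sums (simplex contract).
ROW_SUM_ATOL = 1e-6


@dataclass(frozen=True)
class StageSet:
    """Ordered set of the five scored sleep stages.

    The canonical order Wake, N1, N2, N3, REM (indices 0..4) is fixed so
    that files, arrays and plots are comparable across the package.
    """

    labels: tuple[str, ...] = STAGE_LABELS

    def __post_init__(self):
        if len(self.labels) != N_STAGES or len(set(self.labels)) != N_STAGES:
            raise ValueError("a StageSet must contain exactly 5 distinct labels")

    def index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_STAGES = StageSet()


@dataclass
class Hypnogram:
    """Per-epoch discrete sleep-stage sequence with an artifact mask.

    Parameters
    ----------
    stages
        Stage index (0..4) per epoch, canonical order Wake..REM.
    epoch_seconds
        Epoch duration; 30 s by AASM convention.
    artifact_mask
        True where an epoch was marked as artifact (to be excluded from
        analysis).  Defaults to all-False.
    """

    stages: np.ndarray
    epoch_seconds: float = 30.0
    artifact_mask: np.ndarray | None = None

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=np.intp)
        if self.stages.ndim != 1:
            raise ValueError("stages must be a 1-D sequence")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if self.stages.size and (self.stages.min() < 0 or self.stages.max() >= N_STAGES):
            raise ValueError("stage indices must lie in 0..4")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.stages.shape, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.stages.shape:
                raise ValueError("artifact_mask length must equal stages length")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration_seconds(self) -> float:
        return self.n_epochs * self.epoch_seconds


@dataclass
class HypnodensitySeries:
    """Time-ordered 5-D stage-probability vectors for one channel.

    ``probs`` holds one row per time step; each row lives on the probability
    simplex (non-negative, sums to 1).  ``times`` are window-center
    timestamps in seconds from record start, on a constant step grid.
    ``window_seconds`` is the analysis window each row summarizes (30 s by
    default, sampled every ``step_seconds``).
    """

    times: np.ndarray
    probs: np.ndarray
    channel: str = ""
    step_seconds: float = 5.0
    window_seconds: float = 30.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_STAGES:
            raise ValueError("probs must be a T x 5 matrix")
        if self.times.shape != (self.probs.shape[0],):
            raise ValueError("times length must equal number of probability rows")

    @property
    def n_frames(self) -> int:
        return int(self.probs.shape[0])

    @property
    def duration_seconds(self) -> float:
        """Time spanned by the frame grid (one step per frame)."""
        return self.n_frames * self.step_seconds

    def mean_vector(self) -> "MeanProbabilityVector":
        return MeanProbabilityVector(values=self.probs.mean(axis=0))


@dataclass(frozen=True)
class MeanProbabilityVector:
    """Per-stage mean probabilities of a series (the x-bar of the correlations)."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (N_STAGES,):
            raise ValueError("a mean probability vector has exactly 5 entries")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_series`: pass/fail plus the first violation."""

    ok: bool
    message: str = ""

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_series(series: HypnodensitySeries, atol: float = ROW_SUM_ATOL) -> ValidationReport:
    """Check the hypnodensity invariants and report the first violation.

    Checks, in order: probabilities within [0, 1], row sums within ``atol``
    of 1, times strictly increasing on a constant step grid.  Never mutates
    the input.
    """
    p = series.probs
    if p.shape[0] == 0:
        return ValidationReport(False, "series is empty")
    if not np.all(np.isfinite(p)):
        bad = int(np.argwhere(~np.isfinite(p))[0][0])
        return ValidationReport(False, f"row {bad} contains non-finite values")
    out = (p < -atol) | (p > 1 + atol)
    if out.any():
        bad = int(np.argwhere(out.any(axis=1))[0][0])
        return ValidationReport(False, f"row {bad} has probabilities outside [0, 1]")
    sums = p.sum(axis=1)
    off = np.abs(sums - 1.0) > atol
    if off.any():
        bad = int(np.argwhere(off)[0][0])
        return ValidationReport(False, f"row {bad} sum {sums[bad]:.6g}")
    t = series.times
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argwhere(dt <= 0)[0][0]) + 1
            return ValidationReport(False, f"times not strictly increasing at row {bad}")
        if not np.allclose(dt, series.step_seconds, rtol=1e-9, atol=1e-9):
            bad = int(np.argwhere(~np.isclose(dt, series.step_seconds))[0][0]) + 1
            return ValidationReport(False, f"time step deviates from step_seconds at row {bad}")
    return ValidationReport(True)


def sliding_window_times(
    record_seconds: float, window_seconds: float, step_seconds: float
) -> np.ndarray:
    """Window-center timestamps for a sliding window fully inside the record.

    Centers lie at ``window/2 + k*step`` for every k such that the k-th
    window fits entirely inside ``[0, record_seconds]``; partial windows are
    never emitted.  A window longer than the record yields an empty array.
    """
    if step_seconds <= 0:
        raise ValueError("step_seconds must be positive")
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    if window_seconds > record_seconds:
        return np.empty(0, dtype=float)
    # k-th window spans [k*step, k*step + window]; fits while k*step + window <= record
    n = int(math.floor((record_seconds - window_seconds) / step_seconds + 1e-9)) + 1
    return window_seconds / 2.0 + step_seconds * np.arange(n)


def hypnogram_to_hypnodensity(
    h: Hypnogram,
    step_seconds: float = 5.0,
    gap_policy: str = "concatenate",
    channel: str = "",
):
    """One-hot (degenerate) hypnodensity of a hypnogram.

    Each output row is the one-hot vector of the epoch covering its window
    center, sampled every ``step_seconds`` (which must divide the epoch
    duration).  Artifact epochs are dropped; ``gap_policy`` controls what
    happens at the resulting gaps:

    - ``"concatenate"`` (default): remaining epochs are concatenated on a
      contiguous time base (a warning is logged), returning one series —
      the form the lagged correlations expect.
    - ``"split"``: the record is split at gaps, returning a list of series
      with original timestamps.
    """
    if gap_policy not in ("concatenate", "split"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    ratio = h.epoch_seconds / step_seconds
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("step_seconds must divide epoch_seconds")
    per_epoch = int(round(ratio))
    eye = np.eye(N_STAGES)

    def _segment(stage_run: np.ndarray, t0: float) -> HypnodensitySeries:
        rows = np.repeat(eye[stage_run], per_epoch, axis=0)
        times = t0 + step_seconds / 2.0 + step_seconds * np.arange(rows.shape[0])
        return HypnodensitySeries(
            times=times, probs=rows, channel=channel,
            step_seconds=step_seconds, window_seconds=step_seconds,
        )

    keep = ~h.artifact_mask
    if gap_policy == "concatenate":
        if not keep.all():
            logger.warning(
                "dropping %d artifact epoch(s) and concatenating the remainder; "
                "the correlation time base is contiguous but not wall-clock",
                int((~keep).sum()),
            )
        return _segment(h.stages[keep], 0.0)

    # split policy: contiguous runs of kept epochs, original timestamps
    segments: list[HypnodensitySeries] = []
    i = 0
    n = h.n_epochs
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j]:
            j += 1
        segments.append(_segment(h.stages[i:j], i * h.epoch_seconds))
        i = j
    return segments


def hypnodensity_to_hypnogram(series: HypnodensitySeries) -> Hypnogram:
    """Collapse a hypnodensity to the most-probable-stage sequence.

    Per-row argmax; exact ties are broken toward the lowest canonical stage
    index (numpy argmax convention).  The resulting epoch duration equals
    the series step.
    """
    stages = np.argmax(series.probs, axis=1)
    return Hypnogram(stages=stages, epoch_seconds=series.step_seconds)


def train_test_split_datasets(
    n_datasets: int, train_fraction: float, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random dataset-level train/test split.

    The train size is ``n * fraction`` rounded half-DOWN, so that 68
    datasets at 80% give the conventional 54/14 partition.  The partition is
    disjoint, exhaustive and deterministic for a given seed; indices are
    returned sorted.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n_datasets < 2:
        raise ValueError("need at least 2 datasets to split")
    n_train = int(math.ceil(n_datasets * train_fraction - 0.5))
    n_train = min(max(n_train, 1), n_datasets - 1)
    perm = np.random.default_rng(seed).permutation(n_datasets)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
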