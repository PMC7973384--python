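"""Shared fixtures and independent brute-force oracles.

The oracles transcribe the defining formulas directly (explicit Python
loops over time and lag indices, per-pair distance tables) and are kept
free of any code path they are used to check.
"""

import numpy as np
import pytest

from hypnocycle import HypnodensitySeries


def oracle_lagged_correlation(x: np.ndarray, y: np.ndarray, n_lags: int) -> np.ndarray:
    """Naive double-loop vectorial lagged correlation of T x 5 matrices.

    Numerator: (1/(T−τ)) Σ_t (x_t − x̄)·(y_{t+τ} − ȳ); denominator:
    sqrt of the product of the per-series (1/T) Σ ||·−mean||² terms.
    """
    T = x.shape[0]
    xb = x.mean(axis=0)
    yb = y.mean(axis=0)
    dx = sum(float(np.dot(x[t] - xb, x[t] - xb)) for t in range(T)) / T
    dy = sum(float(np.dot(y[t] - yb, y[t] - yb)) for t in range(T)) / T
    out = np.empty(n_lags)
    for tau in range(n_lags):
        acc = 0.0
        for t in range(T - tau):
            acc += float(np.dot(x[t] - xb, y[t + tau] - yb))
        out[tau] = (acc / (T - tau)) / np.sqrt(dx * dy)
    return out


def oracle_gdv(points: np.ndarray, labels: np.ndarray, rescale: float = 0.5) -> float:
    """Per-pair distance-table GDV with explicit loops."""
    mu = points.mean(axis=0)
    sd = points.std(axis=0)
    keep = sd > 0
    z = rescale * (points[:, keep] - mu[keep]) / sd[keep]
    classes = list(np.unique(labels))
    intra = []
    for c in classes:
        g = z[labels == c]
        dists = [
            float(np.linalg.norm(g[i] - g[j]))
            for i in range(len(g))
            for j in range(i + 1, len(g))
        ]
        intra.append(np.mean(dists))
    inter = []
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            ga = z[labels == classes[a]]
            gb = z[labels == classes[b]]
            inter.append(np.mean([float(np.linalg.norm(p - q)) for p in ga for q in gb]))
    return float((np.mean(intra) - np.mean(inter)) / np.sqrt(keep.sum()))


def random_simplex_series(
    T: int, seed: int, step: float = 5.0, channel: str = ""
) -> HypnodensitySeries:
    """A valid random hypnodensity series (Dirichlet rows)."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(5, 0.8), size=T)
    times = step / 2.0 + step * np.arange(T)
    return HypnodensitySeries(times=times, probs=probs, step_seconds=step, channel=channel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
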