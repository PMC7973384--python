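"""Cross-correlate hypnodensities of multiple EEG channels.

Three channels observe the same night with channel-specific stage biases
and independent softmax noise.  Their pairwise cross-correlations peak at
lag zero — the stage pattern carries no time shift between scalp sites —
and the correlation matrix figure mirrors the channel-similarity view used
for full-night recordings.
"""

import os

import numpy as np

import hypnocycle as hc

os.makedirs("scratch", exist_ok=True)

hypnogram = hc.simulate_hypnogram(hc.CyclicSleepModel(cycle_period=90 * 60.0), seed=5)
noise = hc.NoiseModel(channel_bias=dict(hc.DEFAULT_CHANNEL_BIAS))
channels = hc.simulate_multichannel(hypnogram, noise=noise,
                                    channels=("C4", "F4", "O2"), seed=6)

for i in range(3):
    for j in range(i + 1, 3):
        curve = hc.crosscorrelation(channels[i], channels[j],
                                    max_lag=60 * 60.0, symmetric=True)
        peak = curve.lags[np.argmax(curve.values)]
        print(f"{channels[i].channel} x {channels[j].channel}: "
              f"max r = {curve.values.max():.3f} at lag {peak / 60:.1f} min")

summary = hc.channel_correlation_summary(channels, max_lag=150 * 60.0)
path = hc.plot_correlation(summary, "scratch/channel_matrix.png")
print(f"wrote correlation-matrix figure to {path}")
print("-> peaks at lag 0 mean all channels carry the same stage sequence;")
print("   mean Wake probability per channel:",
      {c.channel: round(float(c.probs[:, 0].mean()), 3) for c in channels})
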