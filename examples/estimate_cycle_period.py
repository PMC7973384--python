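"""Estimate an individual sleep-cycle period from a hypnodensity series.

Simulates one 8-hour synthetic night with a 75-minute ultradian cycle,
converts it to a softmax-like hypnodensity at 5-s resolution, computes the
vectorial auto-correlation and reads the cycle period off its first local
side-maximum.
"""

import hypnocycle as hc

model = hc.CyclicSleepModel(cycle_period=75 * 60.0, total_duration=8 * 3600.0)
hypnogram = hc.simulate_hypnogram(model, seed=42)
series = hc.simulate_noisy_hypnodensity(hypnogram, channel="C4", seed=43)

curve = hc.autocorrelation(series, max_lag=240 * 60.0)
estimate = hc.detect_local_maxima(curve, min_lag=30 * 60.0)

print(f"r(0) = {curve.values[0]:.3f}   (unit by definition)")
print(f"detected maxima at {[round(float(l) / 60, 1) for l in estimate.maxima_lags]} min")
print(f"estimated sleep-cycle period: {estimate.period_seconds / 60:.1f} min")
print("-> the first side-maximum marks one full cycle; later maxima are its repeats")
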