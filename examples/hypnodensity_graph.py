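"""Render a hypnodensity graph and an MDS view of its probability simplex.

The stacked-area hypnodensity graph shows the full stage-probability
distribution over the night (probabilities stack to 1 at every time
point).  The MDS projection of the probability vectors illustrates that
softmax outputs live on a 4-D simplex whose corners are the five stages.
"""

import os

import hypnocycle as hc

os.makedirs("scratch", exist_ok=True)

hypnogram = hc.simulate_hypnogram(hc.CyclicSleepModel(cycle_period=90 * 60.0), seed=11)
channels = hc.simulate_multichannel(hypnogram, channels=("C4", "F4", "O2"), seed=12)

path = hc.plot_hypnodensity(channels, "scratch/hypnodensity.png")
print(f"wrote hypnodensity graph to {path}")

series = channels[0]
subset = series.probs[::20]  # every 100 s, keeps the MDS problem small
labels = subset.argmax(axis=1)
projection = hc.mds_project(subset, out_dim=2, seed=0)
path = hc.plot_embedding_projection(
    projection, labels, "scratch/simplex_mds.png",
    label_names=dict(enumerate(hc.STAGE_LABELS)),
)
print(f"wrote MDS projection (stress {projection.stress:.2f}) to {path}")
print("-> clusters sit at simplex corners; points between corners are frames")
print("   where the stage assignment is uncertain")
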