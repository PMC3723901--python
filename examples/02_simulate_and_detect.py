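"""Simulate spontaneous LIF activity and detect the network bursts.

Runs a 31 s simulation of a random network (N = 100, binomial in-degree,
p = 0.2) at the default synaptic weight, discards the 1 s transient, and
prints the activity summary plus the attributes of each detected burst.
"""

from burstnet import (
    BurstConfig,
    InDegreeSpec,
    LIFParams,
    NetworkRecipe,
    detect_bursts,
    simulate_lif,
    summarize,
)

graph = NetworkRecipe("RN", 0.0, InDegreeSpec("binomial", 0.2, 100)).generate(2)
train = simulate_lif(graph, LIFParams(), duration=31_000.0, rng_seed=5)
train = train.drop_transient(1000.0)

config = BurstConfig(model="lif")
summary = summarize(train, config)
print(f"{summary.spike_count} excitatory spikes in 30 s, "
      f"{summary.burst_count} network bursts")
print(f"median burst length {summary.median_burst_length:.2f} ms, "
      f"median burst size {summary.median_burst_size:.0f} spikes\n")

print(f"{'start ms':>10}{'size':>7}{'cells':>7}{'Rs ms':>8}{'Fs ms':>8}{'BL ms':>8}")
for burst in detect_bursts(train, config):
    print(f"{burst.t_start:>10.1f}{burst.size:>7d}{burst.n_participants:>7d}"
          f"{burst.rs:>8.2f}{burst.fs:>8.2f}{burst.length:>8.2f}")
print("\nRs/Fs: half-max half-widths of the Gaussian-smoothed burst profile;")
print("BL = Rs + Fs is the burst length.")
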