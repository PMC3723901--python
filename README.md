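# burstnet

Structure-dynamics analysis of spontaneously bursting neuronal networks.

Cultured neuronal networks — and many *in silico* models of them — exhibit
*network bursts*: short episodes in which a large fraction of the
population fires together. Which aspects of the synaptic wiring diagram
best predict how often and how strongly a network bursts? `burstnet`
answers this question end to end:

1. **Network generation** (`burstnet.netgen`): directed graphs whose
   in-degree sequence is drawn from a binomial or power-law distribution
   with expected mean `p (N − 1)` and then realized *exactly*, wired under
   one of several structural regimes — strictly random (RN),
   Watts-Strogatz ring/torus (WS1/WS2, with locally connected limits
   LCN1/LCN2), feed-forward-motif promotion (FF), and feedback-loop
   promotion (L2/L3/L4/L6). A *strength* parameter in [0, 1] interpolates
   each class continuously from random to its structural extreme.
2. **Graph measures** (`burstnet.measures`): the 21-entry structural
   feature vector — directed clustering coefficient CC (triangle count
   over the maximum attainable in the node's neighborhood, directions
   respected), harmonic path length PL, node-betweenness NB, out-degree
   deviation OD, in/out degree correlation DC, length-to-self LtS (mean
   shortest feedback loop), adjacency spectral radius MEig, the census
   of the 13 connected three-node motifs Mot1–Mot13, and the realized
   average degree.
3. **Dynamics** (`burstnet.lif`, `burstnet.hh`): spontaneous spiking
   under two point-neuron models coupled by chemical synapses with
   Tsodyks–Markram short-term depression — a current-based
   leaky integrate-and-fire network and a conductance-based
   Hodgkin–Huxley-type network (Na, K-dr, slow K, leak; AMPA/NMDA/GABA
   with the [Mg]-dependent NMDA block). Resource depletion, not
   inhibition, terminates the bursts, so both excitatory-only (E) and
   excitatory-inhibitory (EI, 20% inhibitory) networks burst. The
   synaptic weight is calibrated by bisection (`burstnet.calibrate`) so
   that reference random networks burst at 10 bursts/min.
4. **Burst detection** (`burstnet.bursts`): maximal inter-spike-interval
   segmentation (25 ms), spike-count and participation filters, and the
   Gaussian-smoothed burst profile (σ = 2.5 ms on a 0.25 ms grid) whose
   half-max half-widths give the rising slope Rs, falling slope Fs and
   burst length BL = Rs + Fs.
5. **Prediction framework** (`burstnet.predictor`): per-setting Pearson
   correlations between structure and activity; affine least-squares
   predictors `ŷ = a₀ + a₁·degree + Σ aⱼ·gⱼ` fitted on teaching networks
   and scored by mean absolute error on held-out targets over repeated
   splits; Mann-Whitney U-tests between error distributions;
   best-predictor tables and relative-improvement summaries.
6. **Study orchestration** (`burstnet.study`): the 24 simulation
   settings (HH/LIF × E/EI × binomial/power-law × p ∈ {0.16, 0.2, 0.3}),
   the 28-type network roster, deterministic per-run seeding, resumable
   output directories, and a thin `burstnet` command-line interface.

## A worked example

```python
from burstnet import (InDegreeSpec, NetworkRecipe, compute_measures,
                      LIFParams, simulate_lif, BurstConfig, summarize)

spec = InDegreeSpec("binomial", connection_probability=0.2, n_nodes=100)
graph = NetworkRecipe("WS1", strength=0.6, in_degree=spec).generate(rng_seed=1)

m = compute_measures(graph)
print(f"CC={m.cc:.3f}  PL={m.pl:.3f}  MEig={m.meig:.2f}  Mot5={m.mot[4]}")

train = simulate_lif(graph, LIFParams(), duration=31_000.0, rng_seed=5)
s = summarize(train.drop_transient(1000.0), BurstConfig(model="lif"))
print(f"{s.burst_count} bursts, median length {s.median_burst_length:.1f} ms")
```

prints (seeds as shown):

```
CC=0.270  PL=1.687  MEig=19.45  Mot5=1678
9 bursts, median length 17.8 ms
```

A partially rewired ring keeps noticeably more clustering than a random
network (CC 0.27 vs ≈ 0.20) at an almost unchanged path length, and at
the default calibrated weight this more clustered network bursts well
above the 10 bursts/min reference rate (9 bursts in 30 s), each burst
~18 ms long — the structure-to-dynamics effect the prediction framework
quantifies.

The `examples/` directory holds one short narrative script per
capability (generation + measures, simulation + burst detection, weight
calibration, prediction framework); each prints the numbers it computes
and a line on what they mean.

## Command line

```bash
burstnet generate -c FF -s 1.0 -n 100 -p 0.2 -o ff.edges
burstnet measure ff.edges
burstnet simulate ff.edges --model lif --duration 31000 -o ff.spikes
burstnet detect ff.spikes --model lif --max-isi 25
burstnet run-all --config study.yaml --outdir out --seed 1
```

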