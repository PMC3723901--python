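# Methods

This note documents the models, conventions and numerical choices behind
`burstnet`, including the places where the design was genuinely open and
what the package chose.

## Network generation

All generators share one contract: an in-degree is drawn per node and then
realized exactly — node `i` ends up with precisely `degree[i]` distinct
presynaptic partners, self-connections excluded. Holding the in-degree
distribution fixed across structural regimes is what makes the downstream
comparison fair: in-degree variance by itself strongly shapes network
dynamics, so it must not be a confound.

**In-degree laws.** `binomial` draws `Bin(N − 1, p)` — one Bernoulli trial
per potential presynaptic partner, which is the natural reading of a
"binomial in-degree with connection probability p" once self-loops are
excluded. `powerlaw` draws from the truncated discrete law
`P(k) ∝ k^(−α)` on `[k_min, N − 1]` with `k_min = 2`; the exponent α is
solved numerically (Brent's method on the exact truncated mean) so the
distribution mean equals `p (N − 1)` — for N = 100, p = 0.2 this gives
α ≈ 1.14. The exponent is therefore a derived quantity, not a free
parameter; an unattainable target mean raises an error.

**Strength.** Every class carries a strength `s ∈ [0, 1]`; `s = 0` must be
*statistically identical* to the strictly random generator (this is an
enforced test invariant), `s = 1` is the class's extreme. For the
Watts-Strogatz classes the mapping to the rewiring probability is linear,
`p_rw = 1 − s`; only the endpoints are externally pinned, and the linear
map is the simplest one honoring them.

**WS1/WS2.** Nodes are embedded on a ring (2-D coordinates) or a torus
(2-D grid nested in 4-D so that the metric wraps), each node is wired to
its `degree[i]` Euclidean-nearest nodes (distance ties broken by lowest
node index), and every edge is independently rewired with probability
`p_rw`, keeping the postsynaptic node fixed and redrawing uniformly on
self/duplicate collisions. The `s = 1` limits are the locally connected
networks LCN1/LCN2. The torus requires a perfect-square N; the default
study uses N = 100 (10 × 10).

**FF.** Inputs are selected sequentially per node; a candidate that
already projects disynaptically onto the node under construction carries
sampling weight `1 + s·W` (`W = 50` by default), so "secured" direct +
disynaptic connections — feed-forward loops — accumulate. The weight
constant is a free parameter: what is externally constrained is only the
qualitative extreme (FF ensembles must maximize the two feed-forward
motif classes against both random and locally connected ensembles, which
the tests check).

**L2/L3/L4/L6.** Edges are added one at a time (nodes visited in random
order, each node's inputs filled sequentially). A candidate `j` for
postsynaptic node `i` is boosted by `1 + s·W` when the current geodesic
distance satisfies `d(i→j) + 1 ≡ 0 (mod k)` — the new edge `j→i` then
closes a feedback loop of the promoted length `k`, and the congruence
(rather than equality with `k − 1` alone) keeps an emergent layered
structure self-consistent. Any other finite distance would create a loop
of a discredited length; those candidates are suppressed to
`(1 − s) + ε·s` with `ε = 10⁻³`. Unreachable candidates keep weight 1.
Two caveats are worth stating. First, the suppressed-candidate weight
must equal 1 at `s = 0` for the random-limit invariant to hold, which
fixes the interpolation's form. Second, loop promotion is density
limited: with mean degree ≈ 20 in a 100-node network, a perfect
6-layering is impossible (layers of ~17 nodes cannot supply 20 inputs
each), so excess edges necessarily create shortcuts; L2 and L3 reach
their nominal length-to-self exactly (2 and 3), L4 and L6 move toward
but do not reach theirs. The enforced property is relative: the loopy
ensemble's mean LtS is closer to the promoted length than the random
ensemble's.

## Graph measures

* **CC** uses the directed (Fagiolo-style) convention consistent with
  "making an edge bidirectional doubles the counted triangles": node
  `i`'s directed-triangle count is `((A + Aᵀ)³)ᵢᵢ / 2`, normalized by
  `d_tot(d_tot − 1) − 2·d_bidir`, the count attainable if the
  neighborhood were fully bidirectionally connected. The network CC
  averages over nodes with more than one neighbor; with no eligible node
  the convention is 0.
* **PL** is the harmonic mean of pairwise geodesic distances; unreachable
  pairs contribute zero reciprocal, a totally disconnected graph reports
  an `inf` sentinel.
* **NB** is mean Brandes betweenness with fractional credit for tied
  geodesics (endpoints excluded).
* **LtS** aggregates per-node shortest feedback-loop lengths by the
  *harmonic* mean, mirroring PL's treatment of infinities (nodes on no
  cycle contribute zero reciprocal). The aggregation rule was an open
  choice — an arithmetic mean is undefined as soon as one node is
  acyclic — and the harmonic mean degrades gracefully instead.
* **MEig** is the spectral radius of the binary adjacency (real for a
  non-negative matrix).
* **Mot1–Mot13** is the census of the 13 weakly connected three-node
  isomorphism classes, each unordered triple classified by its full
  induced subgraph. The numbering is by edge count with the feed-forward
  loop fixed at Mot5 (the explicit adjacency patterns are documented in
  `burstnet.measures`). The census is computed with a numba kernel over
  a precomputed 64-entry code table; betweenness and distance matrices
  go through igraph's C implementations. All of these are validated
  against brute-force enumeration oracles on graphs with n ≤ 12.
* Infinite PL/LtS sentinels and undefined degree correlations (constant
  degree vectors → sentinel 0 with a flag) are excluded listwise, with a
  logged count, before any regression.

## Neuron models

Supplementary parameter tables for the original models were not
available, so both models use a documented **reference parameter set**
taken from their canonical sources, exposed entirely through
`LIFParams` / `HHParams`; everything downstream is calibrated on burst
rates rather than raw traces, which makes the analysis robust to the
exact parameter values.

**LIF** (current-based, after the classic recurrent network of depressing
synapses): membrane time constant 30 ms, threshold 15 mV above rest,
reset 13.5 mV, refractory period 3 ms, synaptic current decay 3 ms.
Excitatory synapses are depressing two-state Tsodyks-Markram resources
(`U = 0.5`, `τ_rec = 800 ms`); inhibitory synapses are facilitating
(`U = 0.04`, `τ_rec = 100 ms`, `τ_facil = 1000 ms`) and weighted
`−3 J`. The stochastic drive is white noise injected through the synaptic
current variable, i.e. the membrane sees noise low-pass filtered at the
synaptic time constant. This choice (rather than injecting white noise
directly into the voltage) makes the voltage a C¹ process, and the
spontaneous threshold-crossing rate then converges under time-step
refinement (halving `dt` from the default 0.1 ms moves the rate by < 5 %,
an enforced test); a rough diffusion hitting a hard threshold would not
have that property. The amplitude default (14 mV·ms^-½) was set once so
an isolated neuron fires at ~0.4 Hz, in the intended 0.1–1 Hz range.

**HH** (conductance-based, Golomb-type single compartment): transient
sodium with instantaneous activation (m∞³h), delayed-rectifier potassium
(n⁴), a slow potassium current (τ_z = 75 ms) providing adaptation, and
leak (g_L = 0.05 mS/cm², E_L = −70 mV); AMPA (τ = 2 ms), NMDA (τ = 100
ms, voltage-dependent magnesium block with [Mg] = 1 mM) and GABA-A
(τ = 5 ms) conductances, with Tsodyks-Markram depression on the
excitatory conductances and an NMDA/AMPA ratio of 0.15. The noise is a
Brownian voltage increment (2 mV·ms^-½ default, isolated rate ~0.3 Hz).
Integration is Euler–Maruyama at `dt = 0.025 ms`; the voltage
nonlinearities are evaluated through piecewise-linear lookup tables on a
0.01 mV grid (an order-of-magnitude speedup with no visible effect at
this step size). Spikes are suprathreshold (−30 mV) events: inside the
simulation each suprathreshold excursion contributes the time of its
maximum (between spikes the membrane repolarizes well below −30 mV, so
excursion maxima and windowed local maxima coincide); the standalone
trace detector implements the windowed local-maximum rule (window of 20
samples per side, ±0.5 ms, earliest sample wins on plateaus) for
externally recorded traces. Shifting the threshold by ±1 mV changes
detected counts by under 1 % (enforced test).

**Calibration.** One synaptic weight per (model, population) is found by
bisection so that the reference ensemble — random networks, binomial
in-degree, p = 0.2, N = 100 — bursts at 10 bursts/min; each bisection
iterate averages over freshly generated networks and noise realizations
(5 one-minute simulations by default, ±15 % stopping tolerance). That
weight is then frozen for all connection probabilities and in-degree
shapes of the setting family, which is what makes burst rates vary
systematically with p. E and EI networks are calibrated separately.
The burst rate is monotone in the weight throughout the 0–60 bursts/min
regime (enforced test), though the onset of bursting is steep: below a
critical weight recurrent excitation cannot ignite population events, a
few tens of percent above it bursts come several times per minute.
Ensemble averaging inside each iterate is what makes bisection reliable
despite this steepness.

**Simulation protocol.** 61 s per network, with the first second
discarded as a transient before any analysis. Activity measures (spike
count, burst count, median burst length, median burst size) come from
the excitatory population only, and structural measures of EI networks
from the induced excitatory-excitatory subgraph.

## Burst detection

Spikes of the excitatory population are segmented into maximal runs with
consecutive inter-spike gaps ≤ 25 ms. Candidates with fewer than
`⌈f_s·N_E⌉` spikes or fewer than `⌈0.25·N_E⌉` participating neurons are
discarded; the spike-fraction default is model-specific (`f_s = 0.5` for
HH, whose intrinsically bursting cells emit more spikes per event, and
`0.25` for LIF). The exact published filter constants were not legible
in the source material; these defaults pass the planted-burst fixtures
while rejecting single-neuron events, and both fractions are
configurable. The burst profile is the sum of unit Gaussians (σ = 2.5
ms, truncated at ±5σ) centered on the spike times, evaluated on a 0.25
ms grid spanning first to last spike; half-maximum crossings are located
by linear interpolation between grid points and snapped back to the
grid. BL = Rs + Fs is deliberately robust: adding one spike at the
existing peak moves BL by at most two grid steps (enforced test).

## Prediction framework

Within one simulation setting, all network types are pooled and the
Pearson correlation between each (graph measure, activity measure) pair
is computed. Measures whose absolute mean correlation exceeds 0.25 for
some activity property in both the binomial and the power-law setting
families are retained, after which PL is dropped in favour of NB and
Mot13 in favour of CC (near-duplicates, r ≳ 0.9).

Predictors are affine in the chosen measures, always including the
realized average degree (so the *null* predictor is degree-only), fitted
by ordinary least squares (`numpy.linalg.lstsq`; rank deficiency falls
back to the minimum-norm solution with a warning). An optional
diagonally quadratic variant augments the features with their
element-wise squares. Per repetition (10 by default) the teaching set
resamples 100 networks per type without replacement from a 150-per-type
pool, the target set is regenerated (20 fresh networks per type, or a
caller-supplied factory), and each candidate's mean absolute target
error is recorded. The teaching-pool size and repetition count are
externally pinned; the teaching/target split sizes were not legible and
are configurable defaults. Error distributions are compared with
two-sided Mann-Whitney U-tests (exact method for tie-free samples of
size ≤ 8, asymptotic with tie correction otherwise) at α = 0.05. The
best-predictor table marks the minimum-median-error candidate, with
U-test-indistinguishable candidates sharing the cell and a dash where no
candidate significantly beats the null. Improvement summaries report
`(e_null − e_g)/e_null` and the coprediction analogue
`(e_h − e_{h+g})/e_h` averaged over settings.

## Study runner

`StudyConfig` pins the scale knobs (network size, repetitions per type,
strength grids — WS1/WS2/FF at {0.2, 0.4, 0.6, 0.8, 1.0}, loop classes at
{⅓, ⅔, 1}, giving 28 internal types per structural configuration; a
29th, morphology-grown type can only enter as user-supplied edge-list
files). Every per-run seed is derived from the master seed and the
(setting, recipe, repetition) key through CRC-hashed `SeedSequence`
words, so runs are independent of execution order and worker count,
completed runs are skipped on restart, and adding settings does not
shift existing runs' random streams.

## What the synthetic data do and do not show

The planted-mechanism datasets used to validate the prediction framework
make the burst count an exactly affine (plus Gaussian noise) function of
one structural measure with all other measures independent noise. Real
structure-dynamics data violate both assumptions — measures are mutually
correlated across network types, and the structure-activity relation is
noisy and nonlinear — so passing the recovery test demonstrates that the
framework's bookkeeping (teaching/target splits, error accounting,
U-tests, best-predictor logic) is sound, not that any particular measure
dominates in simulated networks. The latter claim is only supported by
running the full study pipeline.

## Ensemble sizes in the checked reproductions

The structural-correlation reproduction uses 20 networks per type per
configuration in the acceptance script (6 per type in the test suite);
the calibration reproduction uses one-minute recordings in the
acceptance script and 31 s recordings in the tests; the HH burst-count
sweep in the tests uses one 13 s recording per type with rates
extrapolated to per-minute. These sizes are the package's chosen
desk-scale operating points; the full study scale (150 repetitions per
type, one-minute recordings throughout) is available through
`StudyConfig`.

## Known limitations

* Synaptic transmission is instantaneous; no delays, gap junctions or
  long-term plasticity.
* The loop-promoting generator cannot realize pure long-loop structure
  at the study's densities (see above); its extreme networks are
  loop-enriched rather than perfectly layered.
* Burst-filter constants and both models' parameter tables are reference
  choices, not reproductions of unavailable originals; conclusions that
  depend on raw spike counts rather than calibrated burst rates should
  be drawn with care.
* The morphology-grown network class is out of scope; rosters that need
  it must import externally generated edge lists.
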