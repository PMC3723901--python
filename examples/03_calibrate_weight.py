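"""Calibrate the LIF synaptic weight to 10 bursts/min by bisection.

The study protocol pins every model/population combination to the same
operating point: random reference networks (binomial in-degree, p = 0.2)
must burst at 10 bursts/min.  Scaled here to 21 s recordings and 3
simulations per iterate so it runs in about a minute.
"""

from burstnet import LIFParams, calibrate_weight, ensemble_burst_rate, reference_recipe

result = calibrate_weight(
    "lif", reference_recipe(100, 0.2), target_rate=10.0, rng_seed=1,
    n_sims=3, duration=21_000.0,
)
print(f"calibrated weight j_syn = {result.j_syn:.2f} mV "
      f"(ensemble rate {result.rate:.1f} bursts/min)")
print("bisection path:", " -> ".join(f"{j:.1f}:{r:.0f}" for j, r in result.history))

rate = ensemble_burst_rate(
    "lif", reference_recipe(100, 0.2), LIFParams().with_weight(result.j_syn),
    n_sims=5, duration=21_000.0, rng_seed=99,
)
print(f"fresh validation ensemble: {rate:.1f} bursts/min (target 10)")
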