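"""Bisection calibration of the synaptic weight to a target bursting rate.

The study protocol sets each model/population combination into the regime
of spontaneous network bursting by tuning the scalar synaptic weight so
that reference random networks (binomial in-degree, p = 0.2) burst at
10 bursts/min.  The mean bursting frequency is monotonically increasing in
the weight over the regime of interest (0-60 bursts/min), so bisection
applies; each iterate averages the burst rate over an ensemble of freshly
generated reference networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bursts import BurstConfig, summarize
from .hh import HHParams, simulate_hh
from .lif import LIFParams, simulate_lif
from .netgen import InDegreeSpec, NetworkRecipe, assign_populations

__all__ = ["CalibrationResult", "reference_recipe", "ensemble_burst_rate", "calibrate_weight"]


def reference_recipe(n_nodes: int = 100, connection_probability: float = 0.2) -> NetworkRecipe:
    """The RN / binomial / p=0.2 reference ensemble used for tuning."""
    return NetworkRecipe(
        "RN", 0.0, InDegreeSpec("binomial", connection_probability, n_nodes)
    )


@dataclass
class CalibrationResult:
    j_syn: float
    rate: float  # bursts/min at the returned weight
    target_rate: float
    history: list = field(default_factory=list)  # (j, rate) per iterate


def _simulate(model, graph, params, duration, seed):
    if model == "lif":
        return simulate_lif(graph, params, duration, seed)
    if model == "hh":
        return simulate_hh(graph, params, duration, seed)
    raise ValueError(f"unknown model {model!r}")


def ensemble_burst_rate(
    model: str,
    recipe: NetworkRecipe,
    params,
    *,
    population: str = "E",
    inhibitory_fraction: float = 0.2,
    n_sims: int = 5,
    duration: float = 61_000.0,
    transient: float = 1000.0,
    rng_seed: int = 0,
) -> float:
    """Mean bursts/min over ``n_sims`` freshly generated reference networks."""
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(2 * n_sims) % (2**31)
    minutes = (duration - transient) / 60_000.0
    counts = []
    for r in range(n_sims):
        graph = recipe.generate(int(seeds[2 * r]))
        if population == "EI":
            graph = assign_populations(graph, inhibitory_fraction, int(seeds[2 * r]) + 1)
        train = _simulate(model, graph, params, duration, int(seeds[2 * r + 1]))
        s = summarize(train.drop_transient(transient), BurstConfig(model=model))
        counts.append(s.burst_count / minutes)
    return float(np.mean(counts))


def calibrate_weight(
    model: str,
    recipe: NetworkRecipe | None = None,
    target_rate: float = 10.0,
    rng_seed: int = 0,
    *,
    params=None,
    population: str = "E",
    inhibitory_fraction: float = 0.2,
    n_sims: int = 5,
    duration: float = 61_000.0,
    tolerance: float = 0.15,
    max_iter: int = 10,
    max_doublings: int = 6,
) -> CalibrationResult:
    """Find the synaptic weight at which reference networks hit ``target_rate``.

    Starts from the model's default weight, expands a bracket by doubling or
    halving, then bisects; every iterate re-estimates the ensemble-mean
    burst rate on fresh networks and noise realizations.  Stops once the
    rate is within ``tolerance * target_rate`` (or after ``max_iter``
    bisection steps).  Raises ``RuntimeError`` if no bracket is found.
    """
    if target_rate < 0 or target_rate > 60:
        raise ValueError("target rate must lie in the monotone regime 0-60 bursts/min")
    if recipe is None:
        recipe = reference_recipe()
    if params is None:
        params = LIFParams() if model == "lif" else HHParams()
    history: list[tuple[float, float]] = []
    counter = [0]

    def rate_at(j: float) -> float:
        counter[0] += 1
        r = ensemble_burst_rate(
            model, recipe, params.with_weight(j),
            population=population, inhibitory_fraction=inhibitory_fraction,
            n_sims=n_sims, duration=duration,
            rng_seed=np.random.SeedSequence([rng_seed, counter[0]]).generate_state(1)[0] % (2**31),
        )
        history.append((j, r))
        return r

    if target_rate == 0:
        return CalibrationResult(0.0, 0.0, 0.0, [(0.0, 0.0)])

    j = params.j_syn
    r = rate_at(j)
    lo = hi = j
    r_lo = r_hi = r
    for _ in range(max_doublings):
        if r_hi >= target_rate:
            break
        lo, r_lo = hi, r_hi
        hi *= 2.0
        r_hi = rate_at(hi)
    else:
        if r_hi < target_rate:
            raise RuntimeError("no bracket: burst rate below target over the weight range")
    for _ in range(max_doublings):
        if r_lo <= target_rate:
            break
        hi, r_hi = lo, r_lo
        lo /= 2.0
        r_lo = rate_at(lo)
    else:
        if r_lo > target_rate:
            raise RuntimeError("no bracket: burst rate above target over the weight range")

    best_j, best_r = (lo, r_lo) if abs(r_lo - target_rate) < abs(r_hi - target_rate) else (hi, r_hi)
    for _ in range(max_iter):
        if abs(best_r - target_rate) <= tolerance * target_rate:
            break
        mid = 0.5 * (lo + hi)
        r_mid = rate_at(mid)
        if abs(r_mid - target_rate) < abs(best_r - target_rate):
            best_j, best_r = mid, r_mid
        if r_mid < target_rate:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best_j, best_r, target_rate, history)
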