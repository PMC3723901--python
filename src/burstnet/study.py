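"""Study orchestration: settings x network types x repetitions.

Enumerates the network-type roster (random networks, Watts-Strogatz ring
and torus, feed-forward, and loop-promoting classes over their strength
grids), manages reproducible per-run seeds, and drives the full pipeline
generation -> structural measures -> simulation -> burst detection ->
prediction, persisting plain-text artifacts along the way.

Per-run seeds are a pure function of (master seed, setting, recipe,
repetition), so re-running a study directory reproduces it exactly,
completed runs are skipped on restart, and results do not depend on the
order in which runs execute.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bursts import BurstConfig, summarize
from .calibrate import calibrate_weight, reference_recipe
from .graph import DirectedGraph
from .hh import HHParams, simulate_hh
from .lif import LIFParams, simulate_lif
from .measures import compute_measures
from .netgen import InDegreeSpec, NetworkRecipe, assign_populations, excitatory_subgraph
from .predictor import (
    Dataset,
    SimulationSetting,
    best_predictor_table,
    improvement_report,
    run_experiment,
)

__all__ = ["StudyConfig", "enumerate_types", "derive_seed", "run_study", "run_setting"]

logger = logging.getLogger(__name__)

WS_STRENGTHS = (0.2, 0.4, 0.6, 0.8, 1.0)
LOOP_STRENGTHS = (1 / 3, 2 / 3, 1.0)


@dataclass
class StudyConfig:
    """Configuration of a (possibly scaled-down) study run."""

    settings: tuple = ()  # SimulationSetting subset; empty = all 24
    network_size: int = 100
    reps_per_type: int = 150
    ws_strengths: tuple = WS_STRENGTHS
    loop_strengths: tuple = LOOP_STRENGTHS
    inhibitory_fraction: float = 0.2
    duration: float = 61_000.0  # ms
    transient: float = 1000.0  # ms
    calibration_target: float = 10.0  # bursts/min
    calibration_sims: int = 5
    # optional pre-calibrated weights {"MODEL/POP": j_syn}; bypasses bisection
    fixed_weights: dict = field(default_factory=dict)
    master_seed: int = 0
    output_dir: str = "study_out"
    save_artifacts: bool = False  # write per-run edge lists and spike trains
    n_jobs: int = 1  # results are independent of the worker count
    # prediction stage
    candidate_measures: tuple = ("CC", "NB", "OD", "MEig", "Mot5", "Mot12")
    n_repetitions: int = 10
    teaching_size: int = 100
    target_size: int = 20

    def resolved_settings(self) -> tuple[SimulationSetting, ...]:
        return tuple(self.settings) or SimulationSetting.all_settings()


def enumerate_types(config: StudyConfig, in_degree_shape: str, connection_probability: float):
    """The internal network-type roster of one structural configuration.

    RN plus WS1/WS2/FF over the Watts-Strogatz strength grid and
    L2/L3/L4/L6 over the loop grid: 28 recipes at the default grids.
    (Morphology-grown networks are not generated internally; user-supplied
    edge-list graphs can extend the roster.)
    """
    shape = {"BIN": "binomial", "POW": "powerlaw"}[in_degree_shape]
    spec = InDegreeSpec(shape, connection_probability, config.network_size)
    recipes = [NetworkRecipe("RN", 0.0, spec)]
    for cls in ("WS1", "WS2", "FF"):
        recipes += [NetworkRecipe(cls, s, spec) for s in config.ws_strengths]
    for cls in ("L2", "L3", "L4", "L6"):
        recipes += [NetworkRecipe(cls, s, spec) for s in config.loop_strengths]
    return recipes


def derive_seed(master_seed: int, *keys) -> int:
    """Stable per-run seed from the master seed and arbitrary string keys."""
    words = [int(master_seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(words).generate_state(1)[0] % (2**31))


def _simulate(setting: SimulationSetting, graph, j_syn, duration, seed):
    if setting.model == "LIF":
        return simulate_lif(graph, LIFParams().with_weight(j_syn), duration, seed)
    return simulate_hh(graph, HHParams().with_weight(j_syn), duration, seed)


def _one_run(config, setting, recipe, rep, j_syn):
    """Generate -> measure -> simulate -> summarize one network realization."""
    gseed = derive_seed(config.master_seed, setting.label, recipe.name, rep, "graph")
    sseed = derive_seed(config.master_seed, setting.label, recipe.name, rep, "sim")
    graph = recipe.generate(gseed)
    if setting.population == "EI":
        graph = assign_populations(graph, config.inhibitory_fraction, gseed + 1)
        structural = excitatory_subgraph(graph)
    else:
        structural = graph
    m = compute_measures(structural)
    train = _simulate(setting, graph, j_syn, config.duration, sseed)
    s = summarize(train.drop_transient(config.transient),
                  BurstConfig(model=setting.model.lower()))
    row = {"run_id": f"{recipe.name}_r{rep}", "network_type": recipe.name, "rep": rep}
    row.update(m.as_dict())
    row.update(s.as_dict())
    return row, graph, train


def calibrate_setting_weights(config: StudyConfig, settings=None) -> dict:
    """One calibrated weight per (model, population), on the RN/BIN/p=0.2 reference."""
    weights = {}
    for setting in settings or config.resolved_settings():
        key = (setting.model, setting.population)
        if key in weights:
            continue
        fixed = config.fixed_weights.get(f"{setting.model}/{setting.population}")
        if fixed is not None:
            weights[key] = float(fixed)
            continue
        res = calibrate_weight(
            setting.model.lower(),
            reference_recipe(config.network_size),
            config.calibration_target,
            derive_seed(config.master_seed, "calibration", *key),
            population=setting.population,
            inhibitory_fraction=config.inhibitory_fraction,
            n_sims=config.calibration_sims,
            duration=config.duration,
        )
        logger.info("calibrated %s/%s: j_syn=%.4g (rate %.1f/min)",
                    setting.model, setting.population, res.j_syn, res.rate)
        weights[key] = res.j_syn
    return weights


def run_setting(
    config: StudyConfig, setting: SimulationSetting, j_syn: float, outdir: Path
) -> pd.DataFrame:
    """All runs of one simulation setting; resumable via the runs CSV."""
    outdir.mkdir(parents=True, exist_ok=True)
    runs_path = outdir / "runs.csv"
    existing = (
        pd.read_csv(runs_path, float_precision="round_trip")
        if runs_path.exists() else pd.DataFrame()
    )
    done = set(existing["run_id"]) if len(existing) else set()
    recipes = enumerate_types(config, setting.in_degree_shape, setting.connection_probability)
    rows = []
    for recipe in recipes:
        for rep in range(config.reps_per_type):
            run_id = f"{recipe.name}_r{rep}"
            if run_id in done:
                continue
            try:
                row, graph, train = _one_run(config, setting, recipe, rep, j_syn)
            except FloatingPointError as err:  # quarantine, keep going
                logger.error("run %s/%s failed: %s", setting.label, run_id, err)
                continue
            rows.append(row)
            if config.save_artifacts:
                adir = outdir / "artifacts"
                adir.mkdir(exist_ok=True)
                graph.write_edge_list(adir / f"{run_id}.edges")
                train.write(adir / f"{run_id}.spikes")
    frame = pd.concat([existing, pd.DataFrame(rows)], ignore_index=True)
    frame.to_csv(runs_path, index=False)
    return frame


def run_study(config: StudyConfig) -> Path:
    """Run the configured study end to end; returns the output directory.

    Layout: ``<outdir>/manifest.json`` (seeds, weights, parameters),
    ``<outdir>/<setting>/runs.csv`` (one row per network: structural
    measures + activity summary), and per-setting prediction reports
    (error tables, improvement tables, best-predictor matrix).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = config.resolved_settings()
    weights = calibrate_setting_weights(config, settings)
    manifest = {
        "master_seed": config.master_seed,
        "weights": {f"{m}/{p}": j for (m, p), j in weights.items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items() if k != "settings"},
        "settings": [s.label for s in settings],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    experiments = {}
    for setting in settings:
        frame = run_setting(config, setting,
                            weights[(setting.model, setting.population)],
                            outdir / setting.label)
        ds = Dataset(frame, setting)
        candidates = [()] + [(m,) for m in config.candidate_measures]
        for activity in ("burst_count", "median_burst_length"):
            try:
                exp = run_experiment(
                    ds, activity, candidates,
                    n_repetitions=config.n_repetitions,
                    rng_seed=derive_seed(config.master_seed, setting.label, activity, "exp"),
                    teaching_size=min(config.teaching_size, config.reps_per_type),
                    target_size=config.target_size,
                )
            except ValueError as err:
                logger.warning("prediction skipped for %s/%s: %s", setting.label, activity, err)
                continue
            exp.setting = setting
            experiments[(setting.label, activity)] = exp
            exp.errors.to_csv(outdir / setting.label / f"errors_{activity}.csv", index=False)

    if experiments:
        report = improvement_report(experiments)
        report["single"].to_csv(outdir / "improvement_single.csv")
        if len(report["copredict"]):
            report["copredict"].to_csv(outdir / "improvement_copredict.csv")
        try:
            best_predictor_table(experiments).to_csv(outdir / "best_predictors.csv")
        except ValueError as err:  # e.g. too few repetitions for the U-test
            logger.warning("best-predictor table skipped: %s", err)
    return outdir
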