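"""Structure-dynamics prediction framework.

Given per-network structural feature vectors and activity summaries, the
framework quantifies how well each graph measure predicts each activity
property.  Within one *simulation setting* (model x population x in-degree
shape x connection probability) the per-pair Pearson correlation gives a
first screen; affine least-squares predictors

    y_hat = a0 + a1 * degree + a2 * g1 + ... (+ optional squared terms)

are then trained on a teaching set and scored by mean absolute error on a
held-out target set.  The realized average degree is always included to
compensate for in-degree variance, so the *null predictor* uses the degree
alone.  Error distributions over repeated teaching/target splits are
compared with Mann-Whitney U-tests, yielding best-predictor tables and
relative-improvement summaries.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACTIVITY_NAMES",
    "SimulationSetting",
    "Dataset",
    "PredictorModel",
    "PredictionExperiment",
    "correlation",
    "screen_measures",
    "prune_redundant",
    "fit_predictor",
    "evaluate",
    "run_experiment",
    "compare_errors",
    "improvement_report",
    "best_predictor_table",
]

logger = logging.getLogger(__name__)

ACTIVITY_NAMES = ("spike_count", "burst_count", "median_burst_length", "median_burst_size")

CONNECTION_PROBABILITIES = (0.16, 0.2, 0.3)


@dataclass(frozen=True)
class SimulationSetting:
    """One of the 24 model/population/in-degree/connectivity combinations."""

    model: str  # "HH" | "LIF"
    population: str  # "E" | "EI"
    in_degree_shape: str  # "BIN" | "POW"
    connection_probability: float

    def __post_init__(self):
        if self.model not in ("HH", "LIF"):
            raise ValueError("model must be HH or LIF")
        if self.population not in ("E", "EI"):
            raise ValueError("population must be E or EI")
        if self.in_degree_shape not in ("BIN", "POW"):
            raise ValueError("in_degree_shape must be BIN or POW")
        if self.connection_probability not in CONNECTION_PROBABILITIES:
            raise ValueError(f"connection probability must be one of {CONNECTION_PROBABILITIES}")

    @property
    def label(self) -> str:
        return f"{self.model}_{self.population}_{self.in_degree_shape}_p{self.connection_probability:g}"

    @classmethod
    def all_settings(cls) -> tuple["SimulationSetting", ...]:
        return tuple(
            cls(m, pop, shape, p)
            for m in ("HH", "LIF")
            for pop in ("E", "EI")
            for shape in ("BIN", "POW")
            for p in CONNECTION_PROBABILITIES
        )


@dataclass
class Dataset:
    """Per-network rows of one setting: structural measures and activity.

    ``frame`` must contain a ``network_type`` column, the structural
    measure columns (including ``Degree``) and activity columns.  Rows
    with non-finite values in the used columns are excluded listwise by
    :meth:`clean` (infinite path-length / length-to-self sentinels and
    zero-burst activity sentinels), with the exclusion count logged.
    """

    frame: pd.DataFrame
    setting: SimulationSetting | None = None

    def clean(self, columns) -> "Dataset":
        cols = [c for c in columns if c in self.frame.columns]
        finite = np.isfinite(self.frame[cols].to_numpy(dtype=float)).all(axis=1)
        dropped = int((~finite).sum())
        if dropped:
            logger.warning("excluding %d rows with non-finite values in %s", dropped, cols)
        return Dataset(self.frame.loc[finite].reset_index(drop=True), self.setting)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------
def correlation(data: Dataset | pd.DataFrame, property_a: str, property_b: str) -> float:
    """Pearson correlation between two per-network properties of a setting.

    All networks of the setting are pooled.  If either property has zero
    variance the correlation is undefined; the sentinel 0.0 is returned
    with a warning.
    """
    frame = data.frame if isinstance(data, Dataset) else data
    sub = frame[[property_a, property_b]].to_numpy(dtype=float)
    sub = sub[np.isfinite(sub).all(axis=1)]
    if len(sub) < 3:
        raise ValueError("correlation needs at least three finite rows")
    x, y = sub[:, 0], sub[:, 1]
    if x.std() == 0 or y.std() == 0:
        warnings.warn(f"zero variance in {property_a!r} or {property_b!r}; correlation undefined")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def screen_measures(
    correlations: pd.DataFrame,
    threshold: float = 0.25,
    prune: bool = True,
) -> list[str]:
    """Retain measures whose mean correlation clears ``threshold`` in both shapes.

    ``correlations`` has one row per (setting, measure, activity) with
    columns ``shape`` ("BIN"/"POW"), ``measure``, ``activity`` and ``r``.
    A measure is retained when, for at least one activity property, the
    absolute mean correlation over the settings of each in-degree shape
    exceeds the threshold in *both* shapes.  With ``prune``, PL is dropped
    in favour of NB and Mot13 in favour of CC (near-duplicate measures).
    """
    mean_r = correlations.groupby(["shape", "measure", "activity"])["r"].mean().abs()
    retained = []
    for measure in correlations["measure"].unique():
        for activity in correlations["activity"].unique():
            try:
                ok = (
                    mean_r.loc[("BIN", measure, activity)] > threshold
                    and mean_r.loc[("POW", measure, activity)] > threshold
                )
            except KeyError:
                continue
            if ok:
                retained.append(measure)
                break
    return prune_redundant(retained) if prune else retained


def prune_redundant(measures: list[str]) -> list[str]:
    """Drop PL when NB is present and Mot13 when CC is present."""
    out = list(measures)
    if "NB" in out and "PL" in out:
        out.remove("PL")
    if "CC" in out and "Mot13" in out:
        out.remove("Mot13")
    return out


# ---------------------------------------------------------------------------
# affine predictors
# ---------------------------------------------------------------------------
@dataclass
class PredictorModel:
    """Affine (optionally diagonally quadratic) least-squares predictor.

    ``measure_names`` always starts with the realized average degree;
    ``coefficients`` holds the intercept first, then one coefficient per
    feature (and per squared feature if ``quadratic``).
    """

    measure_names: tuple[str, ...]
    coefficients: np.ndarray
    quadratic: bool = False

    def _design(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[list(self.measure_names)].to_numpy(dtype=float)
        cols = [np.ones(len(x)), x]
        if self.quadratic:
            cols.append(x**2)
        return np.column_stack(cols)

    def predict(self, data: Dataset | pd.DataFrame) -> np.ndarray:
        frame = data.frame if isinstance(data, Dataset) else data
        return self._design(frame) @ self.coefficients


def _with_degree(measure_names) -> tuple[str, ...]:
    names = tuple(m for m in measure_names if m != "Degree")
    return ("Degree",) + names


def fit_predictor(
    teaching: Dataset | pd.DataFrame,
    activity_name: str,
    measure_names=(),
    quadratic: bool = False,
) -> PredictorModel:
    """Ordinary least squares fit of the affine predictor on teaching data.

    The realized average degree is automatically included, so an empty
    ``measure_names`` yields the null (degree-only) predictor.  Rank
    deficiency falls back to the minimum-norm solution with a warning.
    """
    frame = teaching.frame if isinstance(teaching, Dataset) else teaching
    names = _with_degree(measure_names)
    model = PredictorModel(names, np.zeros(0), quadratic)
    design = model._design(frame)
    if len(frame) < 2 * design.shape[1]:
        raise ValueError(
            f"need at least {2 * design.shape[1]} teaching rows for {design.shape[1]} coefficients"
        )
    y = frame[activity_name].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; using the minimum-norm solution")
    model.coefficients = coef
    return model


def evaluate(model: PredictorModel, target: Dataset | pd.DataFrame, activity_name: str) -> float:
    """Mean absolute prediction error on the target networks."""
    frame = target.frame if isinstance(target, Dataset) else target
    if len(frame) == 0:
        raise ValueError("target set is empty")
    y = frame[activity_name].to_numpy(dtype=float)
    return float(np.mean(np.abs(model.predict(frame) - y)))


# ---------------------------------------------------------------------------
# repeated teaching/target experiments
# ---------------------------------------------------------------------------
def _candidate_name(measures) -> str:
    measures = tuple(m for m in measures if m != "Degree")
    return "null" if not measures else "+".join(measures)


@dataclass
class PredictionExperiment:
    """Error distributions of candidate predictors over repeated splits."""

    activity_name: str
    errors: pd.DataFrame  # rows = repetitions, columns = candidate names
    candidates: dict = field(default_factory=dict)  # name -> measure tuple
    setting: SimulationSetting | None = None

    def mean_errors(self) -> pd.Series:
        return self.errors.mean(axis=0)

    def median_errors(self) -> pd.Series:
        return self.errors.median(axis=0)

    def u_test(self, name_a: str, name_b: str) -> float:
        return compare_errors(self.errors[name_a].to_numpy(), self.errors[name_b].to_numpy())


def run_experiment(
    pool: Dataset,
    activity_name: str,
    candidates,
    n_repetitions: int = 10,
    rng_seed: int = 0,
    *,
    teaching_size: int = 100,
    target_size: int = 20,
    target_pool: Dataset | None = None,
    target_factory=None,
    quadratic: bool = False,
) -> PredictionExperiment:
    """Repeated teaching/target evaluation of candidate predictors.

    Per repetition the teaching set resamples ``teaching_size`` networks of
    each type (without replacement) from the per-type pool, and the target
    set is regenerated: either drawn by ``target_factory(repetition)`` — a
    callable returning a :class:`Dataset` of fresh networks — or sampled
    from the disjoint ``target_pool`` (defaulting to the pool itself).
    Every candidate is a sequence of measure names (the degree is always
    added); the empty sequence is the null predictor.
    """
    rng = np.random.default_rng(rng_seed)
    cand_map = {_candidate_name(c): tuple(m for m in c if m != "Degree") for c in candidates}
    columns = [c for c in cand_map if c != "null"]
    used_measures = {"Degree", activity_name, *itertools.chain.from_iterable(cand_map.values())}
    pool = pool.clean(used_measures)
    groups = {t: f for t, f in pool.frame.groupby("network_type")}
    short = [t for t, f in groups.items() if len(f) < teaching_size]
    if short:
        raise ValueError(f"teaching pool smaller than teaching_size for types {short}")

    rows = []
    for rep in range(n_repetitions):
        teach = pd.concat(
            [f.sample(n=teaching_size, replace=False, random_state=rng.integers(2**31))
             for f in groups.values()],
            ignore_index=True,
        )
        if target_factory is not None:
            target = target_factory(rep)
            if isinstance(target, Dataset):
                target = target.clean(used_measures)
            else:
                target = Dataset(target).clean(used_measures)
        else:
            src = (target_pool or pool).clean(used_measures)
            target = Dataset(
                pd.concat(
                    [f.sample(n=min(target_size, len(f)), replace=False,
                              random_state=rng.integers(2**31))
                     for _, f in src.frame.groupby("network_type")],
                    ignore_index=True,
                )
            )
        row = {}
        for name, measures in cand_map.items():
            model = fit_predictor(teach, activity_name, measures, quadratic=quadratic)
            row[name] = evaluate(model, target, activity_name)
        rows.append(row)
    errors = pd.DataFrame(rows)
    return PredictionExperiment(activity_name, errors, cand_map)


def compare_errors(errors_a, errors_b) -> float:
    """Two-sided Mann-Whitney U-test p-value between two error samples."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each error sample needs at least three values")
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not _has_ties(a, b)) else "auto"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _has_ties(a, b) -> bool:
    both = np.concatenate([a, b])
    return len(np.unique(both)) < len(both)


# ---------------------------------------------------------------------------
# cross-setting reports
# ---------------------------------------------------------------------------
def improvement_report(experiments: dict) -> dict[str, pd.DataFrame]:
    """Relative error improvements, averaged over simulation settings.

    ``experiments`` maps ``(setting_label, activity_name)`` to a
    :class:`PredictionExperiment` that contains the null predictor plus
    single-measure candidates (and optionally pairs ``g+h``).  Returns

    ``single``
        per (activity, measure): mean over settings and repetitions of
        ``(e_null - e_g) / e_null``,
    ``copredict``
        per (activity, measure): mean over other measures h and settings of
        ``(e_h - e_{h+g}) / e_h`` (only when pair candidates are present).
    """
    single_rows, co_rows = [], []
    for (setting, activity), exp in experiments.items():
        e = exp.errors
        singles = [c for c in e.columns if c != "null" and "+" not in c]
        for g in singles:
            imp = (e["null"] - e[g]) / e["null"]
            single_rows.append({"activity": activity, "measure": g,
                                "setting": setting, "improvement": imp.mean()})
        for g in singles:
            vals = []
            for h in singles:
                if h == g:
                    continue
                pair = "+".join(sorted([g, h]))
                if pair in e.columns:
                    vals.append(((e[h] - e[pair]) / e[h]).mean())
            if vals:
                co_rows.append({"activity": activity, "measure": g,
                                "setting": setting, "improvement": float(np.mean(vals))})
    single = (
        pd.DataFrame(single_rows)
        .groupby(["activity", "measure"])["improvement"].mean().unstack()
        if single_rows else pd.DataFrame()
    )
    co = (
        pd.DataFrame(co_rows)
        .groupby(["activity", "measure"])["improvement"].mean().unstack()
        if co_rows else pd.DataFrame()
    )
    return {"single": single, "copredict": co}


def best_predictor_table(experiments: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Best single-measure predictor per setting x activity cell.

    The minimum-median-error candidate is "best"; any candidate whose
    error distribution is U-test-indistinguishable from it (p >= alpha)
    shares the cell.  A cell shows ``-`` when no candidate is
    significantly better than the null predictor.
    """
    cells = {}
    for (setting, activity), exp in experiments.items():
        e = exp.errors
        singles = [c for c in e.columns if c != "null" and "+" not in c]
        med = e[singles].median()
        best = med.idxmin()
        beats_null = (
            exp.u_test(best, "null") < alpha and med[best] < e["null"].median()
        )
        if not beats_null:
            cells[(setting, activity)] = "-"
            continue
        shared = [c for c in singles if c == best or exp.u_test(best, c) >= alpha]
        cells[(setting, activity)] = "/".join(sorted(shared, key=singles.index))
    table = pd.Series(cells).unstack()
    table.index.name = "setting"
    return table
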