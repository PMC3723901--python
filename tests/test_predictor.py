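"""Prediction framework: correlations, screening, OLS fits, experiments."""

import numpy as np
import pandas as pd
import pytest

from burstnet.predictor import (
    Dataset,
    SimulationSetting,
    best_predictor_table,
    compare_errors,
    correlation,
    evaluate,
    fit_predictor,
    improvement_report,
    prune_redundant,
    run_experiment,
    screen_measures,
)

import oracles


def synthetic_pool(rng, n_types=6, per_type=40, signal="CC", noise=1.0, beta=30.0):
    """Per-network rows with a planted linear mechanism y = f(signal) + noise."""
    rows = []
    for t in range(n_types):
        base_cc = 0.1 + 0.08 * t
        for _ in range(per_type):
            cc = base_cc + rng.normal(0, 0.01)
            row = {
                "network_type": f"T{t}",
                "Degree": 19.8 + rng.normal(0, 0.4),
                "CC": cc,
                "NB": rng.normal(80, 5),
                "OD": rng.normal(4, 0.5),
                "MEig": rng.normal(20, 0.3),
                "Mot5": rng.normal(4000, 300),
                "Mot12": rng.normal(250, 40),
            }
            row["burst_count"] = 2.0 + beta * row[signal] + rng.normal(0, noise)
            rows.append(row)
    return Dataset(pd.DataFrame(rows))


class TestSettings:
    def test_exactly_24_settings(self):
        settings = SimulationSetting.all_settings()
        assert len(settings) == 24
        assert len({s.label for s in settings}) == 24

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            SimulationSetting("HH", "E", "BIN", 0.25)
        with pytest.raises(ValueError):
            SimulationSetting("XX", "E", "BIN", 0.2)


class TestCorrelation:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [3.0, 5.0, 7.0, 9.0]})
        assert correlation(df, "x", "y") == pytest.approx(1.0)

    def test_constant_column_flags_sentinel(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            assert correlation(df, "x", "y") == 0.0

    def test_matches_textbook_one_pass_formula(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": y})
        n = 100
        one_pass = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert correlation(df, "x", "y") == pytest.approx(one_pass, abs=1e-12)


class TestScreening:
    @staticmethod
    def corr_table(mean_by_measure):
        rows = []
        for shape in ("BIN", "POW"):
            for setting in range(12):
                for measure, (r_bin, r_pow) in mean_by_measure.items():
                    rows.append({
                        "shape": shape, "measure": measure, "activity": "burst_count",
                        "r": r_bin if shape == "BIN" else r_pow,
                    })
        return pd.DataFrame(rows)

    def test_reproduces_published_screen_then_prunes(self):
        strong, weak = (0.6, 0.5), (0.1, 0.1)
        table = self.corr_table({
            "CC": strong, "PL": strong, "NB": strong, "OD": strong,
            "MEig": strong, "Mot5": strong, "Mot12": strong, "Mot13": strong,
            "DC": weak, "LtS": weak, "Mot1": weak,
        })
        retained = screen_measures(table, prune=False)
        assert set(retained) == {"CC", "PL", "NB", "OD", "MEig", "Mot5", "Mot12", "Mot13"}
        assert set(screen_measures(table)) == {"CC", "NB", "OD", "MEig", "Mot5", "Mot12"}

    def test_measure_strong_in_one_shape_only_is_dropped(self):
        table = self.corr_table({"OD": (0.6, 0.1)})
        assert screen_measures(table) == []

    def test_zero_threshold_retains_everything(self):
        table = self.corr_table({"CC": (0.01, 0.01), "DC": (0.02, 0.02)})
        assert set(screen_measures(table, threshold=0.0, prune=False)) == {"CC", "DC"}

    def test_prune_requires_the_replacement_measure(self):
        assert prune_redundant(["PL", "Mot13"]) == ["PL", "Mot13"]
        assert prune_redundant(["NB", "PL", "CC", "Mot13"]) == ["NB", "CC"]


class TestFitting:
    def test_exact_affine_recovery(self, rng):
        deg = rng.normal(20, 1, size=30)
        df = pd.DataFrame({"Degree": deg, "y": 3.0 + 2.0 * deg, "network_type": "T"})
        model = fit_predictor(df, "y", ())
        assert model.coefficients == pytest.approx([3.0, 2.0], abs=1e-8)
        assert evaluate(model, df, "y") == pytest.approx(0.0, abs=1e-8)

    def test_coefficients_match_normal_equations(self, rng):
        df = pd.DataFrame({
            "Degree": rng.normal(20, 1, 50),
            "CC": rng.normal(0.2, 0.05, 50),
            "y": rng.normal(size=50),
        })
        model = fit_predictor(df, "y", ("CC",))
        design = np.column_stack([np.ones(50), df["Degree"], df["CC"]])
        expected = oracles.ols_normal_equations_oracle(design, df["y"].to_numpy())
        assert np.allclose(model.coefficients, expected, rtol=1e-8)

    def test_null_predictor_uses_degree_only(self, rng):
        df = pd.DataFrame({"Degree": rng.normal(20, 1, 20), "y": rng.normal(size=20)})
        model = fit_predictor(df, "y", ())
        assert model.measure_names == ("Degree",)
        assert len(model.coefficients) == 2

    def test_quadratic_flag_adds_squared_features(self, rng):
        df = pd.DataFrame({
            "Degree": rng.normal(20, 1, 40),
            "CC": rng.normal(0.2, 0.05, 40),
        })
        df["y"] = 1.0 + df["CC"] ** 2
        model = fit_predictor(df, "y", ("CC",), quadratic=True)
        assert len(model.coefficients) == 5  # 1 + 2 features + 2 squares
        assert evaluate(model, df, "y") < 1e-6

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"Degree": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="teaching rows"):
            fit_predictor(df, "y", ())

    def test_constant_prediction_error_is_one(self):
        model = fit_predictor(
            pd.DataFrame({"Degree": np.zeros(4), "y": [5.0] * 4}), "y", ()
        )
        target = pd.DataFrame({"Degree": [0.0, 0.0], "y": [4.0, 6.0]})
        assert evaluate(model, target, "y") == pytest.approx(1.0)

    def test_teaching_residual_never_grows_with_more_measures(self, rng):
        pool = synthetic_pool(rng).frame
        null_err = evaluate(fit_predictor(pool, "burst_count", ()), pool, "burst_count")
        one = evaluate(fit_predictor(pool, "burst_count", ("CC",)), pool, "burst_count")
        two = evaluate(
            fit_predictor(pool, "burst_count", ("CC", "NB")), pool, "burst_count"
        )
        assert one <= null_err + 1e-12
        assert two <= one + 1e-9


class TestUTest:
    def test_identical_samples_give_maximal_p(self):
        assert compare_errors([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_fully_separated_samples_of_three(self):
        assert compare_errors([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(3, 6)))
        b = rng.normal(size=int(rng.integers(3, 6)))
        assert compare_errors(a, b) == pytest.approx(
            oracles.mann_whitney_exact_oracle(a, b), abs=1e-12
        )

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_errors([1.0], [2.0, 3.0, 4.0])


class TestExperiments:
    def test_deterministic_data_gives_identical_errors(self, rng):
        pool = synthetic_pool(rng, noise=0.0)
        exp = run_experiment(pool, "burst_count", [(), ("CC",)], n_repetitions=4,
                             rng_seed=0, teaching_size=30, target_size=10)
        # the mechanism is exactly linear in CC: error is ~0 every repetition
        assert (exp.errors["CC"] < 1e-6).all()

    def test_reproducible_under_master_seed(self, rng):
        pool = synthetic_pool(rng)
        a = run_experiment(pool, "burst_count", [(), ("CC",)], 3, 42, teaching_size=30)
        b = run_experiment(pool, "burst_count", [(), ("CC",)], 3, 42, teaching_size=30)
        assert a.errors.equals(b.errors)

    def test_pure_noise_measure_brings_no_significant_gain(self, rng):
        pool = synthetic_pool(rng, signal="CC")
        exp = run_experiment(pool, "burst_count", [("CC",), ("CC", "NB")],
                             n_repetitions=8, rng_seed=1, teaching_size=30)
        # NB is noise: adding it to CC must not significantly improve
        assert exp.u_test("CC", "CC+NB") > 0.05

    def test_planted_signal_measure_brings_significant_gain(self, rng):
        pool = synthetic_pool(rng, signal="CC", noise=0.5)
        exp = run_experiment(pool, "burst_count", [(), ("CC",)],
                             n_repetitions=8, rng_seed=2, teaching_size=30)
        assert exp.u_test("null", "CC") < 0.05
        assert exp.errors["CC"].median() < exp.errors["null"].median()

    def test_short_pool_rejected(self, rng):
        pool = synthetic_pool(rng, per_type=5)
        with pytest.raises(ValueError, match="pool smaller"):
            run_experiment(pool, "burst_count", [()], teaching_size=50)


class TestReports:
    @staticmethod
    def experiment_with_errors(errors: dict):
        return type("E", (), {
            "errors": pd.DataFrame(errors),
            "u_test": lambda self, a, b: compare_errors(
                pd.DataFrame(errors)[a], pd.DataFrame(errors)[b]
            ),
        })()

    def test_equal_errors_give_zero_improvement(self):
        e = [4.0, 5.0, 6.0]
        exp = self.experiment_with_errors({"null": e, "CC": e})
        report = improvement_report({("S", "burst_count"): exp})
        assert report["single"].loc["burst_count", "CC"] == pytest.approx(0.0)

    def test_halved_errors_give_fifty_percent(self):
        exp = self.experiment_with_errors({
            "null": [4.0, 6.0, 8.0], "CC": [2.0, 3.0, 4.0]
        })
        report = improvement_report({("S", "burst_count"): exp})
        assert report["single"].loc["burst_count", "CC"] == pytest.approx(0.5)

    def test_coprediction_improvement(self):
        exp = self.experiment_with_errors({
            "null": [4.0, 4.0, 4.0],
            "CC": [2.0, 2.0, 2.0],
            "NB": [4.0, 4.0, 4.0],
            "CC+NB": [2.0, 2.0, 2.0],
        })
        report = improvement_report({("S", "burst_count"): exp})
        # adding CC to NB halves NB's error; adding NB to CC changes nothing
        assert report["copredict"].loc["burst_count", "CC"] == pytest.approx(0.5)
        assert report["copredict"].loc["burst_count", "NB"] == pytest.approx(0.0)

    def test_planted_mechanism_names_cc_best(self, rng):
        pool = synthetic_pool(rng, signal="CC", noise=0.5)
        candidates = [()] + [(m,) for m in ("CC", "NB", "OD", "MEig", "Mot5", "Mot12")]
        exp = run_experiment(pool, "burst_count", candidates, n_repetitions=8,
                             rng_seed=3, teaching_size=30)
        table = best_predictor_table({("S", "burst_count"): exp})
        assert "CC" in table.loc["S", "burst_count"].split("/")

    def test_no_predictor_beats_null_marks_dash(self, rng):
        pool = synthetic_pool(rng, beta=0.0, noise=1.0)  # y independent of measures
        candidates = [(), ("CC",), ("NB",)]
        exp = run_experiment(pool, "burst_count", candidates, n_repetitions=8,
                             rng_seed=4, teaching_size=30)
        table = best_predictor_table({("S", "burst_count"): exp})
        assert table.loc["S", "burst_count"] == "-"
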