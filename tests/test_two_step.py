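import numpy as np
import pandas as pd
import pytest

from hiermort import (
    CountryConfig,
    LearnerSpec,
    SimulationConfig,
    TwoStepModel,
    fit_global,
    fit_local,
    fit_two_step,
    onboard_country,
    predict,
    simulate_portfolio,
)
from hiermort.two_step import residual_spec
from _scenarios import BASIC_GENERATORS


def _two_country_table(seed=0, shift_b=0.0, n=3000, scale=60.0):
    config = SimulationConfig(
        countries=[
            CountryConfig(id="A", n_groups=n, exposure_scale=scale),
            CountryConfig(id="B", n_groups=n, exposure_scale=scale,
                          intercept_shift=shift_b),
        ],
        feature_generators=dict(BASIC_GENERATORS),
        global_features=("age", "gender", "year"),
        seed=seed,
    )
    table, _ = simulate_portfolio(config)
    return table, config.build_schema()


class TestGlobalStage:
    def test_pooled_identical_countries_recover_rate_level(self):
        table, schema = _two_country_table(seed=1, n=8000)
        model = fit_global(table, schema, LearnerSpec(seed=0))
        pred = model.predict_rate(table)
        observed = table.deaths.sum() / table.exposure.sum()
        weighted = np.sum(pred * table.exposure) / table.exposure.sum()
        assert weighted == pytest.approx(observed, rel=0.02)

    def test_single_country_pool_equals_direct_fit(self):
        table, schema = _two_country_table(seed=2)
        only_a = table.for_country("A")
        m1 = fit_global(only_a, schema, LearnerSpec(seed=5))
        m2 = fit_global(only_a.copy(), schema, LearnerSpec(seed=5))
        np.testing.assert_array_equal(m1.predict_rate(only_a), m2.predict_rate(only_a))

    def test_local_columns_ignored_by_global_model(self, small_study):
        _, table, _ = small_study
        schema = table.schema
        train = table.for_country("7")
        model = fit_global(train, schema, LearnerSpec(seed=0, n_trees=20))
        base = model.predict_rate(train)
        shuffled = train.copy()
        rng = np.random.default_rng(0)
        for name in schema.local_names:
            shuffled.data[name] = rng.permutation(shuffled.data[name].to_numpy())
        np.testing.assert_array_equal(model.predict_rate(shuffled), base)

    def test_schema_without_global_features_rejected(self, small_study):
        from hiermort import FeatureSchema, FeatureSpec

        with pytest.raises(Exception):
            FeatureSchema([FeatureSpec("occ", "categorical", "local", frozenset({"A"}))])


class TestLocalStage:
    def test_zero_tree_local_model_is_neutral(self):
        table, schema = _two_country_table(seed=3)
        g = fit_global(table.for_country("A"), schema, LearnerSpec(seed=0))
        b = table.for_country("B")
        loc = fit_local(b, g, schema, LearnerSpec(n_trees=0, seed=0))
        np.testing.assert_allclose(loc.score(b), 0.0, atol=1e-15)

    def test_residual_factor_recovery_at_small_scale(self):
        # country B's rates are twice the fitted global model's predictions
        table, schema = _two_country_table(seed=4, n=12000, scale=80.0)
        spec = LearnerSpec(seed=0)
        g = fit_global(table.for_country("A"), schema, spec)
        b = table.for_country("B")
        rng = np.random.default_rng(99)
        df = b.data.copy()
        df["deaths"] = rng.poisson(2.0 * np.exp(g.score(b)) * b.exposure)
        from hiermort import PortfolioTable

        b2 = PortfolioTable(df, schema)
        loc = fit_local(b2, g, schema, residual_spec(spec))
        h = np.exp(loc.score(b2))
        weighted = np.sum(h * b2.exposure) / b2.exposure.sum()
        assert weighted == pytest.approx(2.0, rel=0.10)

    def test_fully_missing_local_feature_dropped(self, small_study):
        _, table, _ = small_study
        schema = table.schema
        train_5 = table.for_country("5")  # medical_score structurally absent
        g = fit_global(train_5, schema, LearnerSpec(seed=0, n_trees=10))
        loc = fit_local(train_5, g, schema, LearnerSpec(seed=0, n_trees=10))
        assert "medical_score" not in loc.features
        assert "occupation_class" in loc.features

    def test_multi_country_table_rejected(self):
        table, schema = _two_country_table(seed=5)
        g = fit_global(table, schema, LearnerSpec(seed=0, n_trees=5))
        with pytest.raises(ValueError, match="single-country"):
            fit_local(table, g, schema, LearnerSpec(seed=0))

    def test_zero_death_country_warns_and_stays_neutral(self):
        table, schema = _two_country_table(seed=6, n=200)
        b = table.for_country("B")
        df = b.data.copy()
        df["deaths"] = 0
        from hiermort import PortfolioTable

        b0 = PortfolioTable(df, schema)
        g = fit_global(table.for_country("A"), schema, LearnerSpec(seed=0, n_trees=5))
        with pytest.warns(RuntimeWarning):
            loc = fit_local(b0, g, schema, LearnerSpec(seed=0))
        np.testing.assert_allclose(np.exp(loc.score(b0)), 1.0)


class TestTwoStepModel:
    def test_study_fit_has_one_local_model_per_country(self, small_two_step):
        model, _, _ = small_two_step
        assert len(model.local_models) == 8
        assert model.countries == [str(i) for i in range(1, 9)]

    def test_decomposition_identity(self, small_two_step):
        model, train, test = small_two_step
        for part in (train, test):
            g, l = model.decompose(part)
            d_hat = predict(model, part)
            dev = np.abs(np.log(d_hat) - np.log(part.exposure) - (g + l))
            assert dev.max() < 1e-10

    def test_prediction_is_multiplicative_in_stages(self, small_two_step):
        model, train, _ = small_two_step
        g, l = model.decompose(train)
        np.testing.assert_allclose(
            predict(model, train), np.exp(g) * np.exp(l) * train.exposure, rtol=1e-12
        )

    def test_unseen_country_raises_by_name(self, small_two_step, tiny_table):
        model, train, _ = small_two_step
        df = train.data.iloc[:5].copy()
        df["country"] = "atlantis"
        from hiermort import PortfolioTable

        with pytest.raises(KeyError, match="atlantis"):
            predict(model, PortfolioTable(df, train.schema, check=False))

    def test_determinism_of_full_fit(self, small_study):
        _, table, _ = small_study
        train, _ = table.split()
        spec = LearnerSpec(seed=21, n_trees=15)
        p1 = predict(fit_two_step(train, table.schema, spec), train)
        p2 = predict(fit_two_step(train, table.schema, spec), train)
        np.testing.assert_array_equal(p1, p2)

    def test_single_country_fit_works(self):
        table, schema = _two_country_table(seed=7)
        only_a = table.for_country("A")
        model = fit_two_step(only_a, schema, LearnerSpec(seed=0, n_trees=10))
        assert (predict(model, only_a) > 0).all()

    def test_balance_factor_forces_training_ae_to_one(self, small_study):
        _, table, _ = small_study
        train, _ = table.split()
        model = fit_two_step(train, table.schema, LearnerSpec(seed=3, n_trees=10),
                             balance=True)
        d_hat = predict(model, train)
        cc = train.data["country"].to_numpy()
        for country in model.countries:
            sel = cc == country
            assert train.deaths[sel].sum() / d_hat[sel].sum() == pytest.approx(1.0, abs=1e-9)

    def test_save_load_round_trip(self, small_two_step, tmp_path):
        model, train, _ = small_two_step
        model.save(tmp_path / "bundle")
        back = TwoStepModel.load(tmp_path / "bundle")
        np.testing.assert_allclose(predict(back, train), predict(model, train), rtol=1e-12)


class TestOnboarding:
    def test_existing_predictions_bit_identical(self):
        table, schema = _two_country_table(seed=8, shift_b=0.3)
        a, b = table.for_country("A"), table.for_country("B")
        model = fit_two_step(a, schema, LearnerSpec(seed=0, n_trees=10))
        before = predict(model, a)
        grown = onboard_country(model, b, schema, LearnerSpec(seed=1, n_trees=10))
        after = predict(grown, a)
        np.testing.assert_array_equal(before, after)
        assert (predict(grown, b) > 0).all()

    def test_onboarding_existing_country_rejected(self):
        table, schema = _two_country_table(seed=9)
        a = table.for_country("A")
        model = fit_two_step(a, schema, LearnerSpec(seed=0, n_trees=5))
        with pytest.raises(ValueError, match="already"):
            onboard_country(model, a, schema, LearnerSpec(seed=0))

    def test_zero_tree_onboarding_equals_global(self):
        table, schema = _two_country_table(seed=10)
        a, b = table.for_country("A"), table.for_country("B")
        model = fit_two_step(a, schema, LearnerSpec(seed=0, n_trees=10))
        grown = onboard_country(model, b, schema, LearnerSpec(seed=0, n_trees=0))
        np.testing.assert_allclose(
            predict(grown, b), model.global_model.predict_rate(b) * b.exposure, rtol=1e-12
        )
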