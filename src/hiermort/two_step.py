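"""The two-step global/local hierarchical mortality model.

Step 1 (*global*): one boosted Poisson rate model, trained on the pooled
data of all countries using the globally shared features only.  It
captures patterns for which cross-country data is comparable (the age
curve, gender, smoker status, ...).

Step 2 (*local*): one model per country, trained on that country's data
using the global features plus the country's available local features.
Each local model starts from the global model's predicted log-rates as a
per-record initial score (its base score is pinned at 0) and boosts on
the residuals, so it learns a country-specific multiplicative correction
factor ``h_j``.

Because boosting adds tree scores in log-rate space, the combined
prediction factorizes exactly:

    E[D | x, j] = q(x_global) * h_j(x_all) * E

with ``q`` the global rate model and ``h_j`` the local factor.  A
zero-tree local model gives ``h_j == 1`` exactly.  Since a local model's
split thresholds must be justified by that country's own experience, a
data-scarce country's ``h_j`` stays close to 1 — an implicit shrinkage
toward the global pattern — while data-rich countries support stronger
local adjustments.

Onboarding a new country adds one local model and leaves all existing
predictions bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import COUNTRY_COL, FeatureSchema, PortfolioTable
from .encode import APPLY, TRAIN_OOF, TableEncoder, impute_sentinels
from .poisson_learner import FittedLearner, LearnerSpec, fit_rate

__all__ = [
    "StageModel",
    "TwoStepModel",
    "residual_spec",
    "fit_global",
    "fit_local",
    "fit_two_step",
    "predict",
    "onboard_country",
]


def residual_spec(spec: LearnerSpec) -> LearnerSpec:
    """Default local-stage spec derived from a from-scratch spec.

    Two changes, both specific to boosting a *residual* factor on top of
    an initial score: the split-gain threshold is dropped, because a
    uniform country-level correction carries zero split gain and any
    positive threshold leaves it systematically under-absorbed (the
    correction rides into leaf values only through splits that clear the
    threshold on other structure); and the tree budget is halved, which
    bounds the accumulation of leaf-level noise that the missing gain
    threshold would otherwise have pruned.
    """
    from dataclasses import replace

    return replace(spec, min_gain=0.0, n_trees=max(1, spec.n_trees // 2))


@dataclass
class StageModel:
    """One fitted stage: learner + its encoders + the features it uses."""

    learner: FittedLearner
    encoder: TableEncoder
    features: list

    def _prepare(self, table: PortfolioTable) -> pd.DataFrame:
        t = impute_sentinels(table, table.schema)
        t = self.encoder.transform(t, APPLY)
        return t.data[self.features]

    def score(self, table: PortfolioTable) -> np.ndarray:
        """Raw log-rate score (b0 + trees) on a raw table."""
        return self.learner.raw_score(self._prepare(table))

    def predict_rate(self, table: PortfolioTable) -> np.ndarray:
        return np.exp(self.score(table))

    def save(self, directory: Path, name: str) -> None:
        directory = Path(directory)
        self.learner.to_files(directory / f"{name}.lgb.txt", directory / f"{name}.json")
        (directory / f"{name}.encoders.json").write_text(self.encoder.to_json())

    @classmethod
    def load(cls, directory: Path, name: str) -> "StageModel":
        directory = Path(directory)
        learner = FittedLearner.from_files(
            directory / f"{name}.lgb.txt", directory / f"{name}.json"
        )
        encoder = TableEncoder.from_json((directory / f"{name}.encoders.json").read_text())
        return cls(learner=learner, encoder=encoder, features=learner.features)


def _fit_stage(
    train: PortfolioTable,
    features: list,
    spec: LearnerSpec,
    init_log_rate: np.ndarray | None,
    base_score,
    encode_k: int,
    encode_folds: np.ndarray | None,
) -> StageModel:
    schema = train.schema
    imputed = impute_sentinels(train, schema)
    encoder = TableEncoder.fit(
        imputed, features, schema, k=min(encode_k, max(2, len(train))), seed=spec.seed,
        folds=encode_folds,
    )
    X = encoder.transform(imputed, TRAIN_OOF).data[features]
    learner = fit_rate(
        spec, X, train.deaths, train.exposure,
        init_log_rate=init_log_rate, base_score=base_score,
    )
    return StageModel(learner=learner, encoder=encoder, features=features)


def fit_global(
    train: PortfolioTable,
    schema: FeatureSchema,
    spec: LearnerSpec,
    encode_k: int = 5,
    encode_folds: np.ndarray | None = None,
) -> StageModel:
    """Step 1: pooled model on global features only.

    Local feature columns in the table are ignored entirely; predictions
    are invariant to their contents.
    """
    if not schema.global_names:
        raise ValueError("schema declares no global features")
    return _fit_stage(
        train, list(schema.global_names), spec,
        init_log_rate=None, base_score="auto",
        encode_k=encode_k, encode_folds=encode_folds,
    )


def fit_local(
    train_j: PortfolioTable,
    global_model: StageModel,
    schema: FeatureSchema,
    spec: LearnerSpec,
    encode_k: int = 5,
    encode_folds: np.ndarray | None = None,
) -> StageModel:
    """Step 2 for one country: boost the residual factor ``h_j``.

    The per-record initial score is the global model's log-rate and the
    base score is pinned at 0, so a zero-tree local model yields
    ``h_j == 1`` exactly.  Local features entirely missing in the
    country's training data are dropped before fitting.
    """
    countries = train_j.countries
    if len(countries) != 1:
        raise ValueError(f"fit_local expects a single-country table, got {countries}")
    (country,) = countries
    features = list(schema.global_names)
    for name in schema.local_names:
        if schema[name].is_available(country) and train_j.data[name].notna().any():
            features.append(name)
    init = global_model.score(train_j)
    return _fit_stage(
        train_j, features, spec,
        init_log_rate=init, base_score=0.0,
        encode_k=encode_k, encode_folds=encode_folds,
    )


@dataclass
class TwoStepModel:
    """Global stage plus one local stage per onboarded country."""

    global_model: StageModel
    local_models: dict
    schema: FeatureSchema
    balance_log_factors: dict = field(default_factory=dict)

    @property
    def countries(self) -> list:
        return sorted(self.local_models)

    def decompose(self, table: PortfolioTable) -> tuple[np.ndarray, np.ndarray]:
        """(global log score, local log score) per record.

        The local score includes the optional per-country balance factor.
        """
        g = self.global_model.score(table)
        l = np.zeros(len(table), dtype=float)
        country_col = table.data[COUNTRY_COL].to_numpy()
        for country in pd.unique(country_col):
            if country not in self.local_models:
                raise KeyError(
                    f"country {country!r} has no local model; onboard it first"
                )
            mask = country_col == country
            sub = table.subset(table.data[COUNTRY_COL] == country)
            l[mask] = self.local_models[country].score(sub)
            l[mask] += self.balance_log_factors.get(country, 0.0)
        return g, l

    def predict_deaths(self, table: PortfolioTable) -> np.ndarray:
        """D_hat = q(x_global) * h_j(x_all) * E = exp(g + l) * E."""
        g, l = self.decompose(table)
        return np.exp(g + l) * table.exposure

    def predict_rate(self, table: PortfolioTable) -> np.ndarray:
        g, l = self.decompose(table)
        return np.exp(g + l)

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.global_model.save(directory, "global")
        for country, stage in self.local_models.items():
            stage.save(directory, f"local_{country}")
        self.schema.to_json(directory / "schema.json")
        manifest = {
            "countries": [str(c) for c in self.local_models],
            "balance_log_factors": {str(c): v for c, v in self.balance_log_factors.items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "TwoStepModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        schema = FeatureSchema.from_file(directory / "schema.json")
        global_model = StageModel.load(directory, "global")
        local_models = {
            c: StageModel.load(directory, f"local_{c}") for c in manifest["countries"]
        }
        return cls(
            global_model=global_model,
            local_models=local_models,
            schema=schema,
            balance_log_factors=manifest.get("balance_log_factors", {}),
        )


def fit_two_step(
    train: PortfolioTable,
    schema: FeatureSchema,
    global_spec: LearnerSpec,
    local_specs: LearnerSpec | dict | None = None,
    balance: bool = False,
    encode_k: int = 5,
) -> TwoStepModel:
    """Fit the global stage, then one local stage per country present.

    ``local_specs`` may be a single spec shared by all countries or a
    per-country mapping; by default each local stage uses
    :func:`residual_spec` of the global spec.  With ``balance``
    on, a post-hoc scalar factor per country forces the training-set
    actual/expected ratio to 1 (off by default).
    """
    global_model = fit_global(train, schema, global_spec, encode_k=encode_k)
    local_models, balance_factors = {}, {}
    for country in train.countries:
        if isinstance(local_specs, dict):
            spec_j = local_specs.get(country, residual_spec(global_spec))
        elif local_specs is not None:
            spec_j = local_specs
        else:
            spec_j = residual_spec(global_spec)
        train_j = train.for_country(country)
        local_models[country] = fit_local(
            train_j, global_model, schema, spec_j, encode_k=encode_k
        )
        if balance:
            model_j = TwoStepModel(global_model, {country: local_models[country]}, schema)
            d_hat = model_j.predict_deaths(train_j)
            total = train_j.deaths.sum()
            if total > 0 and d_hat.sum() > 0:
                balance_factors[country] = float(np.log(total / d_hat.sum()))
    return TwoStepModel(
        global_model=global_model,
        local_models=local_models,
        schema=schema,
        balance_log_factors=balance_factors,
    )


def predict(model: TwoStepModel, table: PortfolioTable) -> np.ndarray:
    """Per-record predicted death counts (the multiplicative combination)."""
    return model.predict_deaths(table)


def onboard_country(
    model: TwoStepModel,
    train_new: PortfolioTable,
    schema: FeatureSchema,
    spec: LearnerSpec,
) -> TwoStepModel:
    """Add one country's local model; everything already fitted is reused.

    The returned model shares the existing global and local stages, so
    predictions for previously onboarded countries are unchanged.
    """
    countries = train_new.countries
    if len(countries) != 1:
        raise ValueError(f"onboard_country expects a single-country table, got {countries}")
    (country,) = countries
    if country in model.local_models:
        raise ValueError(f"country {country!r} already has a local model")
    local_models = dict(model.local_models)
    local_models[country] = fit_local(train_new, model.global_model, schema, spec)
    return TwoStepModel(
        global_model=model.global_model,
        local_models=local_models,
        schema=schema,
        balance_log_factors=dict(model.balance_log_factors),
    )
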