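"""Benchmark orchestration: tuning, the four-strategy comparison, diagnostics.

Four modelling strategies are compared on a common train/test split,
evaluated per country with RMSE and Poisson log-likelihood on both
splits:

* ``local`` — one independent model per country on that country's data;
* ``two_step`` — pooled global model + per-country residual models;
* ``one_step_single`` — one pooled model, sentinel imputation;
* ``one_step_mice`` — one pooled model per bootstrapped tree-imputation
  of the missing blocks, predictions averaged.

Hyperparameters are tuned by seeded random search over a declared space,
scored by out-of-fold Poisson log-likelihood under grouped k-fold
cross-validation whose folds never split a (country, year) cell.  The
global stage is tuned first; local stages are then tuned against the
global stage's out-of-fold predictions, so no information flows between
stages.  The best-by-metric markers in the report are computed from
unrounded values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .data_model import COUNTRY_COL, FOLD_COL, FeatureSchema, PortfolioTable
from .encode import impute_sentinels
from .imputation_benchmarks import MiceConfig, one_step_mice, one_step_single_value
from .poisson_learner import RATE_FLOOR, LearnerSpec, poisson_loglik, rmse, ae_by_group
from .two_step import _fit_stage, fit_two_step

__all__ = [
    "LOCAL",
    "TWO_STEP",
    "ONE_STEP_SINGLE",
    "ONE_STEP_MICE",
    "ALL_STRATEGIES",
    "BenchmarkConfig",
    "EvaluationReport",
    "country_year_folds",
    "tune",
    "run_benchmark",
    "diagnostics",
]

LOCAL = "local"
TWO_STEP = "two_step"
ONE_STEP_SINGLE = "one_step_single"
ONE_STEP_MICE = "one_step_mice"
ALL_STRATEGIES = (LOCAL, TWO_STEP, ONE_STEP_SINGLE, ONE_STEP_MICE)

NOT_APPLICABLE = "n/a"

#: default random-search space for the boosted learner
DEFAULT_SEARCH_SPACE = {
    "n_trees": [50, 100, 200],
    "learning_rate": [0.05, 0.1, 0.2],
    "max_leaves": [15, 31, 63],
    "min_deaths_per_leaf": [50.0, 100.0, 250.0],
    "min_gain": [0.5, 1.0, 2.0],
}


@dataclass
class BenchmarkConfig:
    """Everything a benchmark run needs besides the data."""

    global_spec: LearnerSpec = field(default_factory=LearnerSpec)
    local_specs: dict | LearnerSpec | None = None
    mice: MiceConfig = field(default_factory=MiceConfig)
    tune_models: bool = False
    search_space: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    budget: int = 25
    n_folds: int = 5
    encode_k: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# grouped cross-validation folds
# ---------------------------------------------------------------------------

def country_year_folds(
    table: PortfolioTable, n_folds: int = 5, seed: int = 0, year_feature: str = "year"
) -> np.ndarray:
    """Per-record fold ids; records sharing (country, year) share a fold.

    Groups are shuffled deterministically and dealt round-robin, so fold
    sizes stay balanced in group count.
    """
    df = table.data
    keys = list(zip(df[COUNTRY_COL].astype(str), df[year_feature].astype(str)))
    groups = sorted(set(keys))
    if len(groups) < n_folds:
        raise ValueError(
            f"only {len(groups)} distinct country-year groups; "
            f"use fewer than {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    fold_of_group = {groups[g]: i % n_folds for i, g in enumerate(order)}
    return np.asarray([fold_of_group[k] for k in keys], dtype=int)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def _sample_specs(base: LearnerSpec, space: dict, budget: int, seed: int) -> list:
    """Budget-many candidate specs; the base spec is always candidate 0."""
    rng = np.random.default_rng(seed)
    candidates = [base]
    for _ in range(max(0, budget - 1)):
        draw = {p: vals[rng.integers(0, len(vals))] for p, vals in space.items()}
        candidates.append(replace(base, **draw))
    return candidates


def _oof_global_scores(
    train: PortfolioTable, schema: FeatureSchema, spec: LearnerSpec,
    folds: np.ndarray, encode_k: int,
) -> np.ndarray:
    scores = np.empty(len(train), dtype=float)
    for f in np.unique(folds):
        fit_part = train.subset(pd.Series(folds != f, index=train.data.index))
        stage = _fit_stage(
            fit_part, list(schema.global_names), spec,
            init_log_rate=None, base_score="auto",
            encode_k=encode_k, encode_folds=None,
        )
        hold = train.subset(pd.Series(folds == f, index=train.data.index))
        scores[folds == f] = stage.score(hold)
    return scores


def tune(
    train: PortfolioTable,
    schema: FeatureSchema,
    search_space: dict | None = None,
    budget: int = 25,
    seed: int = 0,
    base_spec: LearnerSpec | None = None,
    n_folds: int = 5,
    encode_k: int = 5,
) -> tuple[LearnerSpec, dict]:
    """Sequential global-then-local spec search by out-of-fold log-likelihood.

    Returns the best global spec and a per-country map of best local
    specs.  Ties keep the earliest candidate, so a run is reproducible
    given the seed.
    """
    space = search_space if search_space is not None else dict(DEFAULT_SEARCH_SPACE)
    base = base_spec if base_spec is not None else LearnerSpec(seed=seed)
    folds = country_year_folds(train, n_folds=n_folds, seed=seed)
    D, E = train.deaths, train.exposure

    # --- stage 1: global spec ------------------------------------------
    best_global, best_ll = None, -np.inf
    for cand in _sample_specs(base, space, budget, seed):
        ll = 0.0
        for f in np.unique(folds):
            fit_part = train.subset(pd.Series(folds != f, index=train.data.index))
            stage = _fit_stage(
                fit_part, list(schema.global_names), cand,
                init_log_rate=None, base_score="auto",
                encode_k=encode_k, encode_folds=None,
            )
            hold = train.subset(pd.Series(folds == f, index=train.data.index))
            ll += poisson_loglik(D[folds == f], np.exp(stage.score(hold)) * E[folds == f])
        if ll > best_ll:
            best_global, best_ll = cand, ll

    # --- stage 2: local specs against frozen global OOF scores ---------
    oof = _oof_global_scores(train, schema, best_global, folds, encode_k)
    local_specs = {}
    for country in train.countries:
        in_j = (train.data[COUNTRY_COL] == country).to_numpy()
        train_j = train.subset(pd.Series(in_j, index=train.data.index))
        folds_j, oof_j = folds[in_j], oof[in_j]
        D_j, E_j = D[in_j], E[in_j]
        features_j = [n for n in schema.global_names]
        for name in schema.local_names:
            if schema[name].is_available(country) and train_j.data[name].notna().any():
                features_j.append(name)
        best_local, best_ll_j = None, -np.inf
        for cand in _sample_specs(base, space, budget, seed + 1):
            ll = 0.0
            for f in np.unique(folds_j):
                m_fit, m_hold = folds_j != f, folds_j == f
                if not m_fit.any() or not m_hold.any():
                    continue
                fit_part = train_j.subset(pd.Series(m_fit, index=train_j.data.index))
                stage = _fit_stage(
                    fit_part, features_j, cand,
                    init_log_rate=oof_j[m_fit], base_score=0.0,
                    encode_k=encode_k, encode_folds=None,
                )
                hold = train_j.subset(pd.Series(m_hold, index=train_j.data.index))
                d_hat = np.exp(stage.score(hold) + oof_j[m_hold]) * E_j[m_hold]
                ll += poisson_loglik(D_j[m_hold], d_hat)
            if ll > best_ll_j:
                best_local, best_ll_j = cand, ll
        local_specs[country] = best_local
    return best_global, local_specs


# ---------------------------------------------------------------------------
# the four-strategy comparison
# ---------------------------------------------------------------------------

METRICS = ("rmse_train", "rmse_test", "loglik_train", "loglik_test")
#: direction per metric: smaller RMSE is better, larger log-likelihood is
LOWER_IS_BETTER = {"rmse_train": True, "rmse_test": True,
                   "loglik_train": False, "loglik_test": False}


@dataclass
class EvaluationReport:
    """Per-(country, strategy) metrics plus best-strategy markers."""

    results: dict  # country -> strategy -> metric -> float | "n/a"
    best: dict  # country -> metric -> strategy
    metadata: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"results": self.results, "best": self.best, "metadata": self.metadata},
            indent=1, sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(results=d["results"], best=d["best"], metadata=d["metadata"])

    def to_markdown(self) -> str:
        """One table per country: metric rows x strategy columns, best flagged."""
        lines = []
        for country in sorted(self.results, key=str):
            strategies = list(self.results[country])
            lines.append(f"### Country {country}")
            lines.append("| Metric | " + " | ".join(strategies) + " |")
            lines.append("|---" * (len(strategies) + 1) + "|")
            for metric in METRICS:
                cells = []
                for s in strategies:
                    v = self.results[country][s].get(metric, NOT_APPLICABLE)
                    cell = f"{v:.4g}" if isinstance(v, float) else str(v)
                    if self.best.get(country, {}).get(metric) == s:
                        cell = f"**{cell}**"
                    cells.append(cell)
                lines.append(f"| {metric} | " + " | ".join(cells) + " |")
            lines.append("")
        return "\n".join(lines)


def _metrics_by_country(train, test, d_hat_train, d_hat_test) -> dict:
    out = {}
    tr_c = train.data[COUNTRY_COL].to_numpy()
    te_c = test.data[COUNTRY_COL].to_numpy()
    for country in np.unique(tr_c):
        m_tr, m_te = tr_c == country, te_c == country
        if not np.isfinite(d_hat_train[m_tr]).all():
            out[country] = {m: NOT_APPLICABLE for m in METRICS}
            continue
        out[country] = {
            "rmse_train": rmse(train.deaths[m_tr], d_hat_train[m_tr]),
            "rmse_test": rmse(test.deaths[m_te], d_hat_test[m_te]),
            "loglik_train": poisson_loglik(train.deaths[m_tr], d_hat_train[m_tr]),
            "loglik_test": poisson_loglik(test.deaths[m_te], d_hat_test[m_te]),
        }
        out[country]["gap_rmse"] = out[country]["rmse_test"] - out[country]["rmse_train"]
    return out


def run_benchmark(
    table: PortfolioTable,
    schema: FeatureSchema,
    strategies=ALL_STRATEGIES,
    config: BenchmarkConfig | None = None,
) -> EvaluationReport:
    """Fit the requested strategies on the train fold; evaluate per country.

    A strategy infeasible for a country (e.g. a local model where the
    country has no training deaths) is recorded as ``n/a`` and the run
    continues.  Strategies are computed independently of each other.
    """
    config = config if config is not None else BenchmarkConfig()
    unknown = set(strategies) - set(ALL_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    train, test = table.split()

    global_spec, local_specs = config.global_spec, config.local_specs
    if config.tune_models:
        global_spec, local_specs = tune(
            train, schema,
            search_space=config.search_space, budget=config.budget,
            seed=config.seed, base_spec=config.global_spec,
            n_folds=config.n_folds, encode_k=config.encode_k,
        )

    results: dict = {}
    per_strategy: dict = {}
    for strategy in strategies:
        if strategy == TWO_STEP:
            model = fit_two_step(
                train, schema, global_spec, local_specs, encode_k=config.encode_k
            )
            d_tr, d_te = model.predict_deaths(train), model.predict_deaths(test)
        elif strategy == ONE_STEP_SINGLE:
            res = one_step_single_value(train, test, schema, global_spec, config.encode_k)
            d_tr, d_te = res.d_hat_train, res.d_hat_test
        elif strategy == ONE_STEP_MICE:
            res = one_step_mice(
                train, test, schema, global_spec, config.mice, config.encode_k
            )
            d_tr, d_te = res.d_hat_train, res.d_hat_test
        else:  # LOCAL
            d_tr = np.full(len(train), np.nan)
            d_te = np.full(len(test), np.nan)
            for country in train.countries:
                train_j = train.for_country(country)
                if train_j.deaths.sum() == 0:
                    continue  # recorded as n/a downstream
                spec_j = global_spec
                if isinstance(local_specs, dict):
                    spec_j = local_specs.get(country, global_spec)
                elif isinstance(local_specs, LearnerSpec):
                    spec_j = local_specs
                feats = [
                    n for n in schema.names
                    if schema[n].is_available(country) and train_j.data[n].notna().any()
                ]
                stage = _fit_stage(
                    train_j, feats, spec_j,
                    init_log_rate=None, base_score="auto",
                    encode_k=config.encode_k, encode_folds=None,
                )
                m_tr = (train.data[COUNTRY_COL] == country).to_numpy()
                m_te = (test.data[COUNTRY_COL] == country).to_numpy()
                test_j = test.for_country(country)
                d_tr[m_tr] = stage.predict_rate(train_j) * train_j.exposure
                d_te[m_te] = stage.predict_rate(test_j) * test_j.exposure
        per_strategy[strategy] = (d_tr, d_te)
        for country, metrics in _metrics_by_country(train, test, d_tr, d_te).items():
            results.setdefault(country, {})[strategy] = metrics

    best: dict = {}
    for country, by_strategy in results.items():
        best[country] = {}
        for metric in METRICS:
            vals = {
                s: v[metric]
                for s, v in by_strategy.items()
                if isinstance(v[metric], float)
            }
            if not vals:
                continue
            pick = min if LOWER_IS_BETTER[metric] else max
            best[country][metric] = pick(vals, key=vals.get)

    metadata = {
        "strategies": list(strategies),
        "seed": config.seed,
        "tuned": config.tune_models,
        "global_spec": asdict(global_spec),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "total_deaths": float(table.deaths.sum()),
    }
    return EvaluationReport(results=results, best=best, metadata=metadata)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray):
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None  # undefined for constant vectors
    return float(np.corrcoef(x, y)[0, 1])


def _age_bands(ages: np.ndarray, width: int = 10) -> np.ndarray:
    lo = (np.floor(ages / width) * width).astype(int)
    return np.asarray([f"{a}-{a + width - 1}" for a in lo])


def smoothness_score(log_rates: np.ndarray) -> float:
    """Mean absolute second difference — 0 for an exactly log-linear curve."""
    if len(log_rates) < 3:
        return 0.0
    return float(np.mean(np.abs(np.diff(log_rates, n=2))))


def diagnostics(
    train: PortfolioTable,
    d_hat_train: np.ndarray,
    test: PortfolioTable,
    d_hat_test: np.ndarray,
    schema: FeatureSchema,
    rate_fn=None,
    age_feature: str = "age",
    gender_feature: str = "gender",
) -> dict:
    """Overfitting and actuarial-plausibility checks for one strategy.

    Returns train-test metric gaps, the Pearson correlation of predicted
    vs observed death counts, actual/expected ratios by age band and by
    gender, and (if a rate function is supplied) an age-smoothness score:
    the mean absolute second difference of the predicted log-rate over an
    age grid at reference feature values (modal categories / median
    metrics of the training data).
    """
    d_hat_train = np.maximum(np.asarray(d_hat_train, dtype=float), RATE_FLOOR)
    d_hat_test = np.maximum(np.asarray(d_hat_test, dtype=float), RATE_FLOOR)
    out: dict = {
        "rmse_train": rmse(train.deaths, d_hat_train),
        "rmse_test": rmse(test.deaths, d_hat_test),
        "loglik_train": poisson_loglik(train.deaths, d_hat_train),
        "loglik_test": poisson_loglik(test.deaths, d_hat_test),
        "correlation_train": _pearson(train.deaths, d_hat_train),
        "correlation_test": _pearson(test.deaths, d_hat_test),
    }
    out["gap_rmse"] = out["rmse_test"] - out["rmse_train"]
    out["gap_loglik_per_record"] = (
        out["loglik_test"] / len(test) - out["loglik_train"] / len(train)
    )

    ages = train.data[age_feature].to_numpy(dtype=float)
    ae_age, overall = ae_by_group(train.deaths, d_hat_train, _age_bands(ages))
    ae_gender, _ = ae_by_group(
        train.deaths, d_hat_train, train.data[gender_feature].to_numpy()
    )
    out["ae_by_age_band"] = {k: (None if np.isnan(v) else float(v)) for k, v in ae_age.items()}
    out["ae_by_gender"] = {k: (None if np.isnan(v) else float(v)) for k, v in ae_gender.items()}
    out["ae_overall"] = overall

    if rate_fn is not None:
        ref = impute_sentinels(train, schema).data
        row = {}
        for name in schema.names:
            if schema[name].kind == "categorical":
                row[name] = ref[name].mode().iloc[0]
            else:
                row[name] = float(ref[name].median())
        row[COUNTRY_COL] = train.data[COUNTRY_COL].mode().iloc[0]
        lo, hi = int(ages.min()), int(ages.max())
        grid = pd.DataFrame([dict(row, **{age_feature: float(a)}) for a in range(lo, hi + 1)])
        grid["deaths"] = 0
        grid["exposure"] = 1.0
        grid_table = PortfolioTable(grid, schema, check=False)
        out["age_smoothness"] = smoothness_score(np.log(rate_fn(grid_table)))
    return out
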