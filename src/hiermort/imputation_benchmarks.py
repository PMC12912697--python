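"""One-step (early data fusion) competitor strategies.

Both competitors pool all countries into a single training table and fit
one boosted Poisson rate model on global + local features, differing in
how they fill the missing blocks that pooling creates:

* *single-value imputation* — the sentinel fill ("Missing" / -1); fast,
  and missingness itself stays visible to the trees;
* *bootstrapped multiple imputation with decision trees* — draw
  ``n_bootstrap`` bootstrap samples, iterate per-variable tree
  imputation on each (a classification tree for categorical variables, a
  regression tree for metric ones), and for every missing cell draw a
  value uniformly at random from the observed values in the cell's leaf,
  so imputation carries sampling variation rather than a single point
  estimate.  One pooled model is trained per completed dataset and the
  per-record predictions are averaged.

Test tables are completed by replaying the imputation trees fitted on
each bootstrap *training* sample — never refitted on test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data_model import FeatureSchema, PortfolioTable
from .encode import SENTINEL_CATEGORY, SENTINEL_METRIC
from .poisson_learner import LearnerSpec
from .two_step import _fit_stage

__all__ = [
    "MiceConfig",
    "OneStepResult",
    "one_step_single_value",
    "mice_impute",
    "fit_mice",
    "one_step_mice",
]


@dataclass(frozen=True)
class MiceConfig:
    """Bootstrapped tree-imputation settings."""

    n_bootstrap: int = 4
    n_iterations: int = 2
    max_depth: int = 8
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_bootstrap < 1 or self.n_iterations < 1:
            raise ValueError("n_bootstrap and n_iterations must be >= 1")


@dataclass
class OneStepResult:
    """A pooled strategy's fitted model(s) and per-record predictions."""

    d_hat_train: np.ndarray
    d_hat_test: np.ndarray
    models: list
    flagged_features: list = field(default_factory=list)


def one_step_single_value(
    train: PortfolioTable,
    test: PortfolioTable,
    schema: FeatureSchema,
    spec: LearnerSpec,
    encode_k: int = 5,
) -> OneStepResult:
    """Pool all countries; sentinel-fill all missing cells; fit one model.

    All features are retained — cells of features entirely missing within
    a country simply carry sentinels.
    """
    stage = _fit_stage(
        train, list(schema.names), spec,
        init_log_rate=None, base_score="auto",
        encode_k=encode_k, encode_folds=None,
    )
    return OneStepResult(
        d_hat_train=stage.predict_rate(train) * train.exposure,
        d_hat_test=stage.predict_rate(test) * test.exposure,
        models=[stage],
    )


# ---------------------------------------------------------------------------
# bootstrapped decision-tree multiple imputation
# ---------------------------------------------------------------------------

class _OrdinalCodec:
    """Stable category -> integer codes for tree predictors."""

    def __init__(self, table_frames: list, categorical: list):
        self.maps = {}
        for name in categorical:
            values = set()
            for frame in table_frames:
                values.update(frame[name].dropna().unique().tolist())
            values.add(SENTINEL_CATEGORY)
            self.maps[name] = {v: i for i, v in enumerate(sorted(values, key=str))}

    def encode_column(self, name: str, values) -> np.ndarray:
        if name in self.maps:
            return pd.Series(values).map(self.maps[name]).fillna(-1).to_numpy(dtype=float)
        return np.asarray(values, dtype=float)

    def matrix(self, frame: pd.DataFrame, names: list) -> np.ndarray:
        """Encoded float matrix with one column per feature, schema order."""
        return np.column_stack([self.encode_column(n, frame[n].to_numpy()) for n in names])



def _draw_from_leaves(
    leaves: np.ndarray,
    leaf_values: dict,
    kind: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized uniform draw from each leaf's observed-value pool."""
    out = np.empty(len(leaves), dtype=object)
    fallback = SENTINEL_CATEGORY if kind == "categorical" else SENTINEL_METRIC
    for leaf in np.unique(leaves):
        sel = leaves == leaf
        pool = leaf_values.get(int(leaf))
        if pool is None or len(pool) == 0:
            out[sel] = fallback
        else:
            out[sel] = pool[rng.integers(0, len(pool), size=int(sel.sum()))]
    return out

@dataclass
class _ImputationStep:
    """One fitted per-variable tree plus its leaf value pools."""

    variable: str
    tree: object
    leaf_values: dict  # leaf id -> np.ndarray of observed values


class BootstrapImputer:
    """The replayable imputation recipe fitted on one bootstrap sample."""

    def __init__(self, schema: FeatureSchema, codec: _OrdinalCodec, steps: list,
                 sentinel_only: list):
        self.schema = schema
        self.codec = codec
        self.steps = steps  # ordered _ImputationStep sequence (all iterations)
        self.sentinel_only = sentinel_only  # variables 100% missing overall

    def _sentinel_fill(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for name in self.schema.names:
            if self.schema[name].kind == "categorical":
                out[name] = out[name].where(out[name].notna(), SENTINEL_CATEGORY)
            else:
                out[name] = out[name].fillna(SENTINEL_METRIC)
        return out

    def complete(self, frame: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        """Fill a feature frame's missing cells by replaying the steps."""
        names = list(self.schema.names)
        missing_masks = {n: frame[n].isna().to_numpy() for n in names}
        filled = self._sentinel_fill(frame)
        enc = self.codec.matrix(filled, names)
        col_of = {n: i for i, n in enumerate(names)}
        for step in self.steps:
            v = step.variable
            miss = missing_masks[v]
            if not miss.any():
                continue
            X = np.delete(enc, col_of[v], axis=1)
            leaves = step.tree.apply(X[miss])
            drawn = _draw_from_leaves(leaves, step.leaf_values, self.schema[v].kind, rng)
            col = filled[v].to_numpy(dtype=object)
            col[miss] = drawn
            if self.schema[v].kind == "metric":
                col = col.astype(float)
            filled[v] = col
            enc[:, col_of[v]] = self.codec.encode_column(v, col)
        return filled


def _fit_bootstrap_imputer(
    features: pd.DataFrame,
    schema: FeatureSchema,
    config: MiceConfig,
    rng: np.random.Generator,
) -> tuple[BootstrapImputer, pd.DataFrame]:
    """Fit trees on one bootstrap resample; return the recipe and the
    completed copy of the *original* feature frame."""
    n = len(features)
    codec = _OrdinalCodec([features], schema.categorical_names())
    boot_idx = rng.integers(0, n, size=n)
    boot = features.iloc[boot_idx].reset_index(drop=True)

    missing_vars = [name for name in schema.names if features[name].isna().any()]
    sentinel_only = [name for name in missing_vars if features[name].isna().all()]
    impute_vars = [name for name in missing_vars if name not in sentinel_only]

    imputer = BootstrapImputer(schema, codec, steps=[], sentinel_only=sentinel_only)
    boot_missing = {v: boot[v].isna().to_numpy() for v in impute_vars}
    boot_filled = imputer._sentinel_fill(boot)

    orig_missing = {v: features[v].isna().to_numpy() for v in impute_vars}
    orig_filled = imputer._sentinel_fill(features)

    names = list(schema.names)
    col_of = {n: i for i, n in enumerate(names)}
    enc_b = codec.matrix(boot_filled, names)
    enc_o = codec.matrix(orig_filled, names)

    for _ in range(config.n_iterations):
        for v in impute_vars:
            obs = ~boot_missing[v]
            if not obs.any():  # bootstrap happened to resample only missing rows
                continue
            Xb = np.delete(enc_b, col_of[v], axis=1)
            y_obs = boot[v].to_numpy()[obs]
            if schema[v].kind == "categorical":
                tree = DecisionTreeClassifier(
                    max_depth=config.max_depth,
                    min_samples_leaf=config.min_samples_leaf,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                tree.fit(Xb[obs], y_obs.astype(str))
            else:
                tree = DecisionTreeRegressor(
                    max_depth=config.max_depth,
                    min_samples_leaf=config.min_samples_leaf,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                tree.fit(Xb[obs], y_obs.astype(float))
            obs_leaves = tree.apply(Xb[obs])
            leaf_values = {
                int(leaf): y_obs[obs_leaves == leaf] for leaf in np.unique(obs_leaves)
            }
            step = _ImputationStep(variable=v, tree=tree, leaf_values=leaf_values)
            imputer.steps.append(step)

            # refresh the bootstrap working copy with draws from this tree
            miss_b = boot_missing[v]
            if miss_b.any():
                leaves_b = tree.apply(Xb[miss_b])
                drawn = _draw_from_leaves(leaves_b, leaf_values, schema[v].kind, rng)
                col = boot_filled[v].to_numpy(dtype=object)
                col[miss_b] = drawn
                boot_filled[v] = col.astype(float) if schema[v].kind == "metric" else col
                enc_b[:, col_of[v]] = codec.encode_column(v, boot_filled[v].to_numpy())

            # and the completed copy of the original table
            miss_o = orig_missing[v]
            if miss_o.any():
                Xo = np.delete(enc_o, col_of[v], axis=1)
                leaves_o = tree.apply(Xo[miss_o])
                drawn = _draw_from_leaves(leaves_o, leaf_values, schema[v].kind, rng)
                col = orig_filled[v].to_numpy(dtype=object)
                col[miss_o] = drawn
                orig_filled[v] = col.astype(float) if schema[v].kind == "metric" else col
                enc_o[:, col_of[v]] = codec.encode_column(v, orig_filled[v].to_numpy())

    return imputer, orig_filled


def fit_mice(
    table: PortfolioTable, schema: FeatureSchema, config: MiceConfig
) -> tuple[list, list]:
    """(completed tables, replayable imputers), one pair per bootstrap.

    Only originally-missing cells differ from the input; observed cells
    are bit-identical across all completed copies.  Variables that are
    100% missing overall cannot be tree-imputed: they are sentinel-filled
    and flagged on the imputer.
    """
    if len(table) < 1:
        raise ValueError("table must have at least one record")
    feature_frame = table.data[schema.names]
    rng = np.random.default_rng(config.seed)
    completed, imputers = [], []
    for _ in range(config.n_bootstrap):
        imputer, filled = _fit_bootstrap_imputer(feature_frame, schema, config, rng)
        df = table.data.copy()
        for name in schema.names:
            df[name] = filled[name].to_numpy()
        completed.append(PortfolioTable(df, schema, check=False))
        imputers.append(imputer)
    return completed, imputers


def mice_impute(
    table: PortfolioTable, schema: FeatureSchema, config: MiceConfig
) -> list:
    """``n_bootstrap`` completed copies of the original table."""
    completed, _ = fit_mice(table, schema, config)
    return completed


def one_step_mice(
    train: PortfolioTable,
    test: PortfolioTable,
    schema: FeatureSchema,
    spec: LearnerSpec,
    config: MiceConfig,
    encode_k: int = 5,
) -> OneStepResult:
    """Fit one pooled model per completed training table; average D_hat.

    Each bootstrap's imputation recipe also completes the test table, so
    test predictions never leak test information into the imputation.
    """
    completed_train, imputers = fit_mice(train, schema, config)
    rng = np.random.default_rng(config.seed + 1)
    preds_train, preds_test, models = [], [], []
    flagged = sorted({v for imp in imputers for v in imp.sentinel_only})
    for comp, imp in zip(completed_train, imputers):
        stage = _fit_stage(
            comp, list(schema.names), spec,
            init_log_rate=None, base_score="auto",
            encode_k=encode_k, encode_folds=None,
        )
        models.append(stage)
        preds_train.append(stage.predict_rate(comp) * comp.exposure)
        test_filled = imp.complete(test.data[schema.names], rng)
        test_df = test.data.copy()
        for name in schema.names:
            test_df[name] = test_filled[name].to_numpy()
        completed_test = PortfolioTable(test_df, schema, check=False)
        preds_test.append(stage.predict_rate(completed_test) * completed_test.exposure)
    return OneStepResult(
        d_hat_train=np.mean(preds_train, axis=0),
        d_hat_test=np.mean(preds_test, axis=0),
        models=models,
        flagged_features=flagged,
    )
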