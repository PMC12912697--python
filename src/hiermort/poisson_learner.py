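"""Boosted-tree Poisson rate learner and evaluation metrics.

The learner estimates a mortality rate ``mu(x)`` (deaths per life-year)
from aggregated records.  Gradient-boosting libraries do not expose an
offset term, so the Poisson-with-offset model is fitted equivalently as a
*weighted rate regression*: target ``D/E``, observation weights ``E``,
Poisson objective.  The two parameterizations share the same likelihood,
so an intercept-only fit returns exactly the portfolio rate
``sum(D)/sum(E)`` and per-category fits match a Poisson GLM with offset
``log E``.

A per-record *initial score* (a starting log-rate) can be supplied; the
ensemble then boosts from it, modelling only the residual factor.  This
is the device the two-step model uses to continue boosting from the
global model's predictions.

All predictions are ``exp(base score + initial score + tree scores)`` and
therefore strictly positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import lightgbm as lgb
import numpy as np
import pandas as pd

__all__ = [
    "RATE_FLOOR",
    "LearnerSpec",
    "FittedLearner",
    "fit_rate",
    "predict_rate",
    "poisson_loglik",
    "rmse",
    "ae_by_group",
]

#: predicted rates are floored here before logs are taken in metrics
RATE_FLOOR = 1e-12


@dataclass(frozen=True)
class LearnerSpec:
    """Hyperparameters of the boosted Poisson rate learner.

    ``min_exposure_per_leaf`` (life-years) and ``min_deaths_per_leaf``
    guard against leaves supported by too little experience; they are
    enforced through the boosting library's minimum-hessian-per-leaf
    constraint, whose Poisson hessian is (approximately) the expected
    death count of a leaf.  ``min_gain`` is the minimum loss reduction a
    split must achieve — the evidence threshold that makes refinements in
    data-scarce segments stay close to their starting score.
    """

    n_trees: int = 100
    learning_rate: float = 0.1
    max_leaves: int = 31
    min_exposure_per_leaf: float = 100.0
    min_deaths_per_leaf: float = 50.0
    min_gain: float = 1.0
    reg_lambda: float = 0.0
    reg_alpha: float = 0.0
    min_records_per_leaf: int = 20
    seed: int = 0
    num_threads: int = 1  # single-threaded training order is deterministic

    def __post_init__(self):
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if min(self.min_exposure_per_leaf, self.min_deaths_per_leaf, self.min_gain) < 0:
            raise ValueError("thresholds must be >= 0")

    def lgb_params(self, portfolio_rate: float) -> dict:
        min_hessian = max(
            self.min_deaths_per_leaf, self.min_exposure_per_leaf * portfolio_rate
        )
        return {
            "objective": "poisson",
            "num_leaves": self.max_leaves,
            "learning_rate": self.learning_rate,
            "min_sum_hessian_in_leaf": min_hessian,
            "min_data_in_leaf": self.min_records_per_leaf,
            "min_gain_to_split": self.min_gain,
            "lambda_l2": self.reg_lambda,
            "lambda_l1": self.reg_alpha,
            "seed": self.seed,
            "deterministic": True,
            "force_row_wise": True,
            "num_threads": self.num_threads,
            "boost_from_average": False,
            "verbosity": -1,
        }


@dataclass
class FittedLearner:
    """A fitted ensemble: base log-rate ``b0`` plus (optional) trees.

    With zero trees the model predicts ``exp(b0 + init)`` everywhere.
    """

    b0: float
    features: list
    spec: LearnerSpec
    booster: lgb.Booster | None = field(default=None, repr=False)

    def raw_score(self, X: pd.DataFrame) -> np.ndarray:
        """b0 + sum of tree scores (the model's own log-rate score)."""
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from input: {missing}")
        Xm = X[self.features]
        score = np.full(len(X), self.b0, dtype=float)
        if self.booster is not None:
            score = score + self.booster.predict(Xm, raw_score=True)
        return score

    # -- serialization ---------------------------------------------------
    def to_files(self, model_path, sidecar_path) -> None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "b0": self.b0,
                    "features": self.features,
                    "spec": asdict(self.spec),
                    "has_booster": self.booster is not None,
                },
                fh,
            )
        if self.booster is not None:
            self.booster.save_model(str(model_path))

    @classmethod
    def from_files(cls, model_path, sidecar_path) -> "FittedLearner":
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        booster = lgb.Booster(model_file=str(model_path)) if meta["has_booster"] else None
        return cls(
            b0=meta["b0"],
            features=meta["features"],
            spec=LearnerSpec(**meta["spec"]),
            booster=booster,
        )


def fit_rate(
    spec: LearnerSpec,
    X: pd.DataFrame,
    D: np.ndarray,
    E: np.ndarray,
    init_log_rate: np.ndarray | None = None,
    base_score: float | str = "auto",
) -> FittedLearner:
    """Fit the Poisson rate ensemble on target D/E with weights E.

    ``base_score='auto'`` initializes b0 at ``log(sum(D)/sum(E))`` when no
    per-record initial score is given, and at 0 otherwise (so a zero-tree
    model passes the initial score through unchanged).  Deterministic
    given the spec's seed and thread configuration.
    """
    D = np.asarray(D, dtype=float)
    E = np.asarray(E, dtype=float)
    if len(X) != len(D) or len(D) != len(E):
        raise ValueError("X, D, E must be aligned")
    if np.any(D < 0):
        raise ValueError("negative death counts")
    if np.any(E <= 0):
        raise ValueError("non-positive exposures")
    if init_log_rate is not None:
        init_log_rate = np.asarray(init_log_rate, dtype=float)
        if len(init_log_rate) != len(D):
            raise ValueError("init_log_rate not aligned")

    portfolio_rate = max(D.sum() / E.sum(), RATE_FLOOR)
    if base_score == "auto":
        b0 = float(np.log(portfolio_rate)) if init_log_rate is None else 0.0
    else:
        b0 = float(base_score)

    features = list(X.columns)
    if D.sum() == 0 and spec.n_trees > 0:
        warnings.warn(
            "all death counts are zero; returning the floored portfolio-rate model",
            RuntimeWarning,
            stacklevel=2,
        )
        return FittedLearner(b0=b0, features=features, spec=spec)
    if spec.n_trees == 0:
        return FittedLearner(b0=b0, features=features, spec=spec)

    init = np.full(len(D), b0, dtype=float)
    if init_log_rate is not None:
        init = init + init_log_rate
    dataset = lgb.Dataset(
        X[features],
        label=D / E,
        weight=E,
        init_score=init,
        params={"verbosity": -1},
        free_raw_data=True,
    )
    booster = lgb.train(
        spec.lgb_params(portfolio_rate),
        dataset,
        num_boost_round=spec.n_trees,
    )
    return FittedLearner(b0=b0, features=features, spec=spec, booster=booster)


def predict_rate(
    model: FittedLearner,
    X: pd.DataFrame,
    init_log_rate: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted rate ``exp(b0 + init + tree scores)``; strictly positive."""
    score = model.raw_score(X)
    if init_log_rate is not None:
        score = score + np.asarray(init_log_rate, dtype=float)
    return np.exp(score)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def poisson_loglik(D: np.ndarray, D_hat: np.ndarray) -> float:
    """Poisson log-likelihood (up to the D-only constant): sum D log D_hat - D_hat.

    Larger is better.  Predicted counts must be strictly positive.
    """
    D = np.asarray(D, dtype=float)
    D_hat = np.asarray(D_hat, dtype=float)
    if len(D) != len(D_hat):
        raise ValueError("D and D_hat must be aligned")
    if np.any(D_hat <= 0):
        raise ValueError("predicted counts must be strictly positive")
    # D=0 terms contribute -D_hat; xlogy handles 0*log cleanly
    from scipy.special import xlogy

    return float(np.sum(xlogy(D, D_hat) - D_hat))


def rmse(D: np.ndarray, D_hat: np.ndarray) -> float:
    """Root-mean-square error of predicted vs observed death counts."""
    D = np.asarray(D, dtype=float)
    D_hat = np.asarray(D_hat, dtype=float)
    if len(D) == 0:
        raise ValueError("empty input")
    if len(D) != len(D_hat):
        raise ValueError("D and D_hat must be aligned")
    return float(np.sqrt(np.mean((D_hat - D) ** 2)))


def ae_by_group(
    D: np.ndarray, D_hat: np.ndarray, group_labels
) -> tuple[pd.Series, float]:
    """Actual/expected death ratios per group, plus the overall ratio.

    A group with zero expected deaths gets NaN (undefined, not infinity).
    """
    df = pd.DataFrame(
        {"D": np.asarray(D, dtype=float), "Dh": np.asarray(D_hat, dtype=float), "g": group_labels}
    )
    if len(df) == 0:
        raise ValueError("empty input")
    agg = df.groupby("g", sort=True).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = agg["D"] / agg["Dh"]
    ratios = ratios.where(agg["Dh"] > 0, np.nan)
    total_dh = agg["Dh"].sum()
    overall = float(agg["D"].sum() / total_dh) if total_dh > 0 else float("nan")
    return ratios.rename("ae_ratio"), overall
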