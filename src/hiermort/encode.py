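"""Model-ready feature preparation: sentinels and target encoding.

Two explicit steps separate a raw table from a model-ready one:

1. *Sentinel imputation* — missing categorical cells become the literal
   category ``"Missing"``, missing metric cells become ``-1``.  The
   sentinel is an ordinary category afterwards, so trees can use
   missingness itself as a signal, including in interactions.

2. *Target encoding* — each categorical level is replaced by the
   exposure-weighted mean of the target (the observed rate D/E) over
   training records of that level.  To avoid target leakage, training
   tables are transformed *out of fold*: record i's encoded value is the
   category mean computed on the other folds only, so it has exactly zero
   dependence on record i's own target.  New data (test/apply) uses the
   full-training-set means.  Unseen categories fall back to the overall
   training mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureSchema, PortfolioTable

__all__ = [
    "SENTINEL_CATEGORY",
    "SENTINEL_METRIC",
    "impute_sentinels",
    "TargetEncoder",
    "fit_target_encoder",
    "transform",
    "TableEncoder",
]

SENTINEL_CATEGORY = "Missing"
SENTINEL_METRIC = -1.0

TRAIN_OOF = "train_oof"
APPLY = "apply"


def impute_sentinels(table: PortfolioTable, schema: FeatureSchema) -> PortfolioTable:
    """Replace missing cells with sentinels; non-missing cells untouched."""
    df = table.data.copy()
    for name in schema.names:
        if name not in df.columns:
            continue
        if schema[name].kind == "categorical":
            df[name] = df[name].where(df[name].notna(), SENTINEL_CATEGORY)
        else:
            df[name] = df[name].fillna(SENTINEL_METRIC)
    return PortfolioTable(df, schema, check=False)


def _weighted_means(cats, y, w) -> dict:
    s = pd.DataFrame({"c": cats, "wy": w * y, "w": w}).groupby("c", sort=True).sum()
    return (s["wy"] / s["w"]).to_dict()


@dataclass
class TargetEncoder:
    """Per-category target means for one categorical feature.

    ``mapping`` holds full-training-set means (used in ``apply`` mode);
    ``fold_mappings[f]`` holds means computed on the complement of fold
    ``f`` (used for leakage-safe transformation of training records);
    ``fallback`` is the overall (exposure-weighted) training target mean.
    """

    feature: str
    mapping: dict
    fold_mappings: list
    fallback: float
    k: int
    seed: int
    fold_of: np.ndarray = field(repr=False)  # per-training-record fold id

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "feature": self.feature,
                "mapping": self.mapping,
                "fold_mappings": self.fold_mappings,
                "fallback": self.fallback,
                "k": self.k,
                "seed": self.seed,
                "fold_of": np.asarray(self.fold_of).tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TargetEncoder":
        d = json.loads(s)
        d["fold_of"] = np.asarray(d["fold_of"], dtype=int)
        return cls(**d)


def fit_target_encoder(
    train: PortfolioTable,
    feature: str,
    target: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
    weights: np.ndarray | None = None,
    folds: np.ndarray | None = None,
    smoothing: float = 0.0,
) -> TargetEncoder:
    """Fit category -> mean maps on training data, per fold-complement.

    The default target is the observed rate D/E with exposure weights, so
    a category's encoded value is its raw mortality rate sum(D)/sum(E).
    ``folds`` may carry an externally built fold assignment (e.g. grouped
    by country-year); otherwise folds are assigned uniformly at random
    from ``seed``.  ``smoothing`` adds that much pseudo-weight at the
    overall mean to each category (0 = plain conditional means).
    """
    n = len(train)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of training records ({n})")
    cats = train.data[feature].to_numpy()
    y = np.asarray(target, dtype=float) if target is not None else train.deaths / train.exposure
    w = np.asarray(weights, dtype=float) if weights is not None else train.exposure
    if len(y) != n or len(w) != n:
        raise ValueError("target/weights not aligned to training table")

    if folds is not None:
        fold_of = np.asarray(folds, dtype=int)
        if len(fold_of) != n:
            raise ValueError("folds not aligned to training table")
        k = int(fold_of.max()) + 1
    else:
        rng = np.random.default_rng(seed)
        fold_of = rng.integers(0, k, size=n)

    fallback = float(np.sum(w * y) / np.sum(w))

    def smooth(means: dict, cats_sub, w_sub) -> dict:
        if smoothing <= 0:
            return {c: float(v) for c, v in means.items()}
        wsum = pd.Series(w_sub).groupby(pd.Series(cats_sub)).sum()
        return {
            c: float((means[c] * wsum[c] + smoothing * fallback) / (wsum[c] + smoothing))
            for c in means
        }

    mapping = smooth(_weighted_means(cats, y, w), cats, w)
    fold_mappings = []
    for f in range(k):
        comp = fold_of != f
        if comp.any():
            fold_mappings.append(smooth(_weighted_means(cats[comp], y[comp], w[comp]), cats[comp], w[comp]))
        else:
            fold_mappings.append({})
    return TargetEncoder(
        feature=feature,
        mapping=mapping,
        fold_mappings=fold_mappings,
        fallback=fallback,
        k=k,
        seed=seed,
        fold_of=fold_of,
    )


def transform(encoder: TargetEncoder, table: PortfolioTable, mode: str) -> PortfolioTable:
    """Replace the encoder's feature column by encoded reals.

    ``train_oof``: record i gets its category's mean from i's
    fold-complement (requires the table to be the training table the
    encoder was fitted on, in the same order).  ``apply``: full-training
    means, a pure function of the training set.
    """
    df = table.data.copy()
    cats = df[encoder.feature].to_numpy()
    if mode == APPLY:
        encoded = np.asarray([encoder.mapping.get(c, encoder.fallback) for c in cats])
    elif mode == TRAIN_OOF:
        if len(table) != len(encoder.fold_of):
            raise ValueError(
                "train_oof mode requires the training table the encoder was fitted on"
            )
        encoded = np.asarray(
            [
                encoder.fold_mappings[f].get(c, encoder.fallback)
                for c, f in zip(cats, encoder.fold_of)
            ]
        )
    else:
        raise ValueError(f"mode must be {TRAIN_OOF!r} or {APPLY!r}, got {mode!r}")
    df[encoder.feature] = encoded
    return PortfolioTable(df, table.schema, check=False)


@dataclass
class TableEncoder:
    """One :class:`TargetEncoder` per categorical feature of a feature set."""

    encoders: dict

    @classmethod
    def fit(
        cls,
        train: PortfolioTable,
        features,
        schema: FeatureSchema,
        k: int = 5,
        seed: int = 0,
        folds: np.ndarray | None = None,
        smoothing: float = 0.0,
    ) -> "TableEncoder":
        encs = {}
        for name in schema.categorical_names(features):
            encs[name] = fit_target_encoder(
                train, name, k=k, seed=seed, folds=folds, smoothing=smoothing
            )
        return cls(encs)

    def transform(self, table: PortfolioTable, mode: str) -> PortfolioTable:
        out = table
        for enc in self.encoders.values():
            out = transform(enc, out, mode)
        return out

    def to_json(self) -> str:
        return json.dumps({name: json.loads(enc.to_json()) for name, enc in self.encoders.items()})

    @classmethod
    def from_json(cls, s: str) -> "TableEncoder":
        d = json.loads(s)
        return cls({name: TargetEncoder.from_json(json.dumps(e)) for name, e in d.items()})
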