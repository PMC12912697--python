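"""Feature schema, aggregated portfolio tables, I/O, folds and missingness.

The unit of analysis is an *aggregated experience record*: one row per
unique combination of feature values within a country, carrying the summed
death count ``D`` and exposure-in-life-years ``E`` for that combination.
Mortality rates are ``D/E`` (deaths per life-year).

Features are declared in a :class:`FeatureSchema`.  *Global* features are
available and comparable in every country and may never be missing;
*local* features are country-specific and may be missing — either
structurally (a country never collects them, expressed through
``available_in``) or partially within a country.
"""

from __future__ import annotations

import json
from dataclasses import InitVar, dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "PortfolioTable",
    "SchemaError",
    "ValidationError",
    "read_portfolio",
    "write_portfolio",
    "assign_folds",
    "missingness_report",
]

#: reserved (non-feature) column names of a portfolio file
COUNTRY_COL = "country"
DEATHS_COL = "deaths"
EXPOSURE_COL = "exposure"
FOLD_COL = "fold"
RESERVED_COLS = (COUNTRY_COL, DEATHS_COL, EXPOSURE_COL, FOLD_COL)

TRAIN, TEST = "train", "test"


class SchemaError(ValueError):
    """A file or table does not match the declared feature schema."""


class ValidationError(ValueError):
    """Records violate portfolio invariants; offending indices are listed."""

    def __init__(self, message: str, bad_index: list | None = None):
        super().__init__(message)
        self.bad_index = list(bad_index) if bad_index is not None else []


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: its name, measurement kind, scope and availability.

    ``available_in=None`` means "available in every country"; global
    features must use ``None`` (they are complete by design).
    """

    name: str
    kind: str  # "categorical" | "metric"
    scope: str  # "global" | "local"
    available_in: frozenset | None = None

    def __post_init__(self):
        if self.kind not in ("categorical", "metric"):
            raise SchemaError(f"feature {self.name!r}: kind must be categorical|metric")
        if self.scope not in ("global", "local"):
            raise SchemaError(f"feature {self.name!r}: scope must be global|local")
        if self.scope == "global" and self.available_in is not None:
            raise SchemaError(
                f"global feature {self.name!r} must be available in all countries "
                "(available_in must be None)"
            )
        if self.available_in is not None:
            object.__setattr__(self, "available_in", frozenset(self.available_in))

    def is_available(self, country) -> bool:
        return self.available_in is None or country in self.available_in


@dataclass
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` with lookup helpers."""

    features: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        clashes = set(names) & set(RESERVED_COLS)
        if clashes:
            raise SchemaError(f"feature names clash with reserved columns: {sorted(clashes)}")
        if not any(f.scope == "global" for f in self.features):
            raise SchemaError("schema must declare at least one global feature")
        self._by_name = {f.name: f for f in self.features}

    # -- lookups ---------------------------------------------------------
    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def global_names(self) -> list[str]:
        return [f.name for f in self.features if f.scope == "global"]

    @property
    def local_names(self) -> list[str]:
        return [f.name for f in self.features if f.scope == "local"]

    def categorical_names(self, subset=None) -> list[str]:
        names = subset if subset is not None else self.names
        return [n for n in names if self[n].kind == "categorical"]

    def metric_names(self, subset=None) -> list[str]:
        names = subset if subset is not None else self.names
        return [n for n in names if self[n].kind == "metric"]

    def available_names(self, country) -> list[str]:
        """Global features plus the local features country collects."""
        return [f.name for f in self.features if f.is_available(country)]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "scope": f.scope,
                    "available_in": sorted(f.available_in) if f.available_in is not None else None,
                }
                for f in self.features
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        feats = []
        for item in d["features"]:
            avail = item.get("available_in")
            feats.append(
                FeatureSpec(
                    name=item["name"],
                    kind=item["kind"],
                    scope=item["scope"],
                    available_in=frozenset(avail) if avail is not None else None,
                )
            )
        return cls(feats)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "FeatureSchema":
        path = str(path)
        if path.endswith(".json"):
            with open(path) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_yaml(path)


@dataclass
class PortfolioTable:
    """Aggregated experience records backed by a :class:`pandas.DataFrame`.

    Columns: ``country``, one column per schema feature, ``deaths``,
    ``exposure`` and optionally ``fold`` (``train``/``test``).  Missing
    feature cells are NaN; the sentinel substitution ("Missing"/−1) is an
    explicit model-preparation step (see :mod:`hiermort.encode`), so raw and
    model-ready tables stay distinguishable.
    """

    data: pd.DataFrame
    schema: FeatureSchema
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True):
        if check:
            self.validate()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def countries(self) -> list:
        return sorted(self.data[COUNTRY_COL].unique().tolist())

    @property
    def deaths(self) -> np.ndarray:
        return self.data[DEATHS_COL].to_numpy(dtype=float)

    @property
    def exposure(self) -> np.ndarray:
        return self.data[EXPOSURE_COL].to_numpy(dtype=float)

    @property
    def has_folds(self) -> bool:
        return FOLD_COL in self.data.columns and self.data[FOLD_COL].notna().all()

    def subset(self, mask) -> "PortfolioTable":
        # rows of a valid table stay valid; skip re-validation
        return PortfolioTable(self.data.loc[mask].copy(), self.schema, check=False)

    def for_country(self, country) -> "PortfolioTable":
        return self.subset(self.data[COUNTRY_COL] == country)

    def split(self) -> tuple["PortfolioTable", "PortfolioTable"]:
        """(train, test) partition by the fold column."""
        if not self.has_folds:
            raise ValidationError("table has no complete fold assignment")
        return (
            self.subset(self.data[FOLD_COL] == TRAIN),
            self.subset(self.data[FOLD_COL] == TEST),
        )

    def copy(self) -> "PortfolioTable":
        return PortfolioTable(self.data.copy(), self.schema, check=False)

    def validate(self) -> None:
        df = self.data
        missing_cols = [c for c in (COUNTRY_COL, DEATHS_COL, EXPOSURE_COL) if c not in df.columns]
        missing_cols += [n for n in self.schema.names if n not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing mandatory columns: {missing_cols}")

        bad = df.index[~(df[EXPOSURE_COL] > 0)].tolist()
        if bad:
            raise ValidationError(f"non-positive exposure at records {bad}", bad)
        deaths = df[DEATHS_COL]
        bad = df.index[(deaths < 0) | (deaths != np.floor(deaths)) | deaths.isna()].tolist()
        if bad:
            raise ValidationError(f"negative or non-integer deaths at records {bad}", bad)

        for name in self.schema.global_names:
            bad = df.index[df[name].isna()].tolist()
            if bad:
                raise ValidationError(
                    f"global feature {name!r} missing at records {bad} "
                    "(global features may not be missing)",
                    bad,
                )
        # structurally unavailable local features must be missing throughout
        for spec in self.schema.features:
            if spec.scope != "local" or spec.available_in is None:
                continue
            mask = ~df[COUNTRY_COL].isin(spec.available_in)
            bad = df.index[mask & df[spec.name].notna()].tolist()
            if bad:
                raise ValidationError(
                    f"local feature {spec.name!r} has values in countries where the "
                    f"schema marks it unavailable, records {bad}",
                    bad,
                )
        if FOLD_COL in df.columns:
            labelled = df[FOLD_COL].dropna()
            bad = labelled.index[~labelled.isin([TRAIN, TEST])].tolist()
            if bad:
                raise ValidationError(f"fold labels other than train/test at records {bad}", bad)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_portfolio(path, schema: FeatureSchema) -> PortfolioTable:
    """Read a portfolio CSV (or parquet) into a validated table.

    Empty cells encode missing values.  Records violating invariants are
    rejected with a :class:`ValidationError` naming the offending rows —
    never silently dropped.
    """
    path = str(path)
    if path.endswith(".parquet"):
        df = pd.read_parquet(path)
    else:
        dtypes = {n: object for n in schema.categorical_names()}
        dtypes[COUNTRY_COL] = object
        df = pd.read_csv(path, dtype=dtypes, keep_default_na=True)
    return PortfolioTable(df, schema)


def write_portfolio(table: PortfolioTable, path) -> None:
    """Write a portfolio to CSV/parquet; missing cells become empty cells."""
    path = str(path)
    if path.endswith(".parquet"):
        table.data.to_parquet(path, index=False)
    else:
        table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def assign_folds(table: PortfolioTable, train_fraction: float, seed: int) -> PortfolioTable:
    """Assign every record a train/test label, stratified by country.

    Stratification guarantees each country is represented in both splits,
    which per-country evaluation requires.  Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    if len(table) == 0:
        raise ValidationError("cannot assign folds to an empty table")
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    labels = pd.Series(TEST, index=df.index, dtype=object)
    # iterate in sorted country order so the RNG stream is reproducible
    for country in sorted(df[COUNTRY_COL].unique(), key=str):
        idx = df.index[df[COUNTRY_COL] == country].to_numpy()
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        labels.loc[idx[perm[:n_train]]] = TRAIN
    df[FOLD_COL] = labels
    return PortfolioTable(df, table.schema)


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def missingness_report(table: PortfolioTable, schema: FeatureSchema) -> pd.DataFrame:
    """Percentage of missing values per (country, feature).

    Rows are countries, columns schema features, entries in [0, 100].
    Global-feature columns are all zero by the table invariants.
    """
    rows = {}
    for country, grp in table.data.groupby(COUNTRY_COL, sort=True):
        rows[country] = {
            name: 100.0 * grp[name].isna().mean() for name in schema.names
        }
    report = pd.DataFrame.from_dict(rows, orient="index")[schema.names]
    report.index.name = COUNTRY_COL
    return report
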