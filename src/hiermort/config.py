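"""Study configuration, seed derivation and run manifests.

A single master seed drives every stage.  Stage seeds are derived by
hashing ``"{master}:{stage-name}"``, so adding or removing one stage
never shifts another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .imputation_benchmarks import MiceConfig
from .poisson_learner import LearnerSpec

__all__ = ["derive_seed", "StudyConfig", "config_hash"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed in [0, 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class StudyConfig:
    """End-to-end study settings (paths, simulation, specs, seed)."""

    portfolio_path: str = "portfolio.csv"
    truth_path: str = "truth.csv"
    schema_path: str = "schema.yaml"
    model_dir: str = "model"
    report_path: str = "report.json"
    predictions_path: str = "predictions.csv"

    simulation_scale: float = 0.01
    simulation: dict | None = None  # full SimulationConfig dict overrides scale

    train_fraction: float = 0.8
    strategies: list = field(default_factory=lambda: ["local", "two_step", "one_step_single", "one_step_mice"])
    learner: dict = field(default_factory=dict)  # LearnerSpec overrides
    mice: dict = field(default_factory=dict)  # MiceConfig overrides
    tune_models: bool = False
    budget: int = 25
    seed: int = 0

    def learner_spec(self, stage: str) -> LearnerSpec:
        return LearnerSpec(seed=derive_seed(self.seed, stage), **self.learner)

    def mice_config(self) -> MiceConfig:
        return MiceConfig(seed=derive_seed(self.seed, "mice"), **self.mice)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def config_hash(config: StudyConfig) -> str:
    """Stable fingerprint of a config, for run manifests."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
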