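"""Pipeline configuration: one place for every downstream default.

The config is a flat mapping read from YAML; unknown keys are rejected
before any stage runs.  All randomness flows from the named stage seeds
(derived deterministically from ``seed`` when not given explicitly).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig"]

_STAGE_SEEDS = ("landscape", "species", "occurrences", "tree", "traits",
                "sdm", "kmeans")


@dataclass
class PipelineConfig:
    # I/O
    out_dir: str = "runs/demo"
    # Landscape
    nrows: int = 16
    ncols: int = 16
    n_continuous: int = 4
    n_categorical: int = 1
    correlation_length: float = 4.0
    n_codes: int = 5
    nodata_fraction: float = 0.0
    cellsize: float = 500.0
    # Species and survey
    n_species: int = 12
    n_sites: int = 200
    class_thresholds: tuple[float, float] = (0.1, 0.5)
    detection: str | float = "proportional"
    # Traits
    n_continuous_traits: int = 3
    trait_sigma2: float = 0.3
    trait_root_state: float = 0.0
    trait_lognormal: bool = True
    missing_fraction: float = 0.15
    log_transform: tuple[str, ...] = ("SLA", "CH", "RD")
    # SDM
    beta: float = 0.1
    min_presences: int = 5
    sdm_scale: str = "logistic"
    # Abundance and biomass
    weights: tuple[float, float, float] = (0.01, 0.1, 1.0)
    convention: str = "normalized"
    allometric_mode: str = "printed"
    # Regionalization
    k_regions: int = 5
    n_init: int = 10
    # Scenario: additive offsets on climatic layers (layer units)
    scenario: dict[str, float] = field(default_factory=lambda: {"clim1": 0.5})
    # Randomness
    seed: int = 0
    seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.class_thresholds = tuple(self.class_thresholds)
        self.weights = tuple(self.weights)
        self.log_transform = tuple(self.log_transform)
        if len(self.weights) != 3:
            raise ValueError("weights must have exactly 3 entries")
        t1, t2 = self.class_thresholds
        if not t1 < t2:
            raise ValueError("class thresholds must satisfy t1 < t2")
        for i, name in enumerate(_STAGE_SEEDS):
            self.seeds.setdefault(name, int(self.seed) * 1000 + i)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["class_thresholds"] = list(self.class_thresholds)
        doc["weights"] = list(self.weights)
        doc["log_transform"] = list(self.log_transform)
        return doc

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
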