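"""Pipeline-wide configuration.

All tunable parameters of the analysis live in a single
:class:`PipelineConfig` so that a run is fully described by one config
file plus one seed.  Defaults mirror the published analysis protocol
(rarefaction at 800 reads, 10,000 label permutations, 1,000 cluster
bootstraps, 500-tree random forests with 20 candidate features per
split over 500 bootstrap iterations, 0.2% genus prevalence filter).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    rarefaction_depth: int = 800
    n_rarefaction_draws: int = 10
    n_permutations: int = 10_000
    n_cluster_bootstraps: int = 1_000
    rf_n_trees: int = 500
    rf_features_per_node: int = 20
    rf_n_iterations: int = 500
    genus_filter_fraction: float = 0.002
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rarefaction_depth",
            "n_rarefaction_draws",
            "n_permutations",
            "n_cluster_bootstraps",
            "rf_n_trees",
            "rf_features_per_node",
            "rf_n_iterations",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if not 0.0 < self.genus_filter_fraction < 1.0:
            raise ValueError(
                f"genus_filter_fraction must lie in (0, 1), got {self.genus_filter_fraction}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def ci_profile(cls, **overrides) -> "PipelineConfig":
        """Reduced-cost profile for routine runs; same analyses, smaller
        Monte-Carlo sizes (permutations, bootstraps, forest iterations)."""
        params = dict(
            n_permutations=1_000,
            n_cluster_bootstraps=200,
            rf_n_trees=100,
            rf_n_iterations=100,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
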