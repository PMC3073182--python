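"""Pipeline configuration: every tunable constant in one place.

Defaults are the constants used throughout the analysis: t > 3.0 for the
process layer (roughly p = 0.001 under a normal null), gene sets of at most
30 genes, a 20% side-effect frequency cutoff, at least 2 drugs per side
effect, 1,000 permutations, and significance at p < 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    t_threshold: float = 3.0
    max_set_genes: int = 30
    min_freq: float = 0.2
    inclusive_freq: bool = True  # ">= min_freq"; False makes the cutoff strict
    min_drugs: int = 2
    n_perm: int = 1000
    alpha: float = 0.05
    plus_one: bool = False  # +1 correction on empirical p-values
    aggregation: str = "union"  # or "max_t": one edge per (drug, process)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if not 0.0 <= self.min_freq <= 1.0:
            raise ValueError("min_freq must be in [0, 1]")
        if self.min_drugs < 2:
            raise ValueError("min_drugs must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.aggregation not in ("union", "max_t"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
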