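"""Pipeline configuration: every tunable threshold in one place.

Defaults follow common practice for cross-study DEG meta-analysis:
DEGs at FDR <= 0.05 and |log2FC| >= 0.5; genes must recur in at least
five conditions before entering the vote count; "frequent" genes recur
in at least half of all conditions; temporal categories take the upper
quartile of per-group detection frequency; GO terms pass at
q <= 1e-5 with >= 3% representation; networks use 1000-tree ensembles
with a 1000-round permutation null.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # differential expression
    fdr_max: float = 0.05
    lfc_min: float = 0.5
    cpm_filter: float = 1.0          # gene dropped iff CPM < this in more than half of samples
    logfc_prior_scale: float = 0.125  # prior count, as multiple of mean library proportion
    logcpm_prior: float = 2.0

    # meta-classification
    min_condition_count: int = 5
    frequent_fraction: float = 0.5
    consistency_fraction: float = 0.5
    tf_consistency_fraction: float = 0.8
    quartile: float = 0.75
    quartile_nonzero_only: bool = True

    # condition taxonomy (minutes / umol m-2 s-1 / days)
    short_max_min: float = 90.0
    long_min_min: float = 120.0
    long_days_min_min: float = 1440.0
    medium_max_min: float = 960.0
    intensity_moderate_min: float = 500.0
    intensity_intensive_min: float = 950.0
    intensity_severe_min: float = 1500.0
    intensity_max: float = 2000.0
    age_mature_min: float = 21.0
    age_mature_max: float = 30.0
    clustering_min_cpm: float = 3.0

    # GO enrichment
    q_max: float = 1e-5
    representation_min: float = 0.03

    # GRN
    min_module_size: int = 30
    min_correlation: float = 0.30
    module_cut_height: float = 0.99
    scale_free_r2: float = 0.8
    soft_power_fallback: int = 6
    n_trees: int = 1000
    n_shuffle: int = 1000
    density: float = 0.065
    perm_alpha: float = 0.05

    # bookkeeping
    seed: int = 0
    exclude_experiments: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in (
            "fdr_max", "frequent_fraction", "consistency_fraction",
            "tf_consistency_fraction", "quartile", "q_max",
            "representation_min", "density", "perm_alpha",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        self.exclude_experiments = tuple(self.exclude_experiments)

    # -- (de)serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_experiments"] = list(d["exclude_experiments"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        """Stable short digest of the full configuration (for table headers)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
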