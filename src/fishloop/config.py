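"""Pipeline configuration: every threshold of the caller in one place.

Defaults are the published operating point of the method: reference cutoff
at 25 Kb of 1D separation, candidates at 100 Kb - 1 Mb, a 25-50 Kb local
neighborhood, Welch two-sample t-test, FDR < 10%, clustering gap of twice
the bin resolution, and contact-frequency floors of 1/3 (summits) and 1/2
(singletons).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .loop_call import CallConfig
from .loop_test import NeighborhoodSpec


@dataclass
class PipelineConfig:
    d0: int = 25_000                  # bp separation defining the cutoff
    neighbor_lower: int = 25_000      # bp, inclusive
    neighbor_upper: int = 50_000      # bp, inclusive
    min_sep: int = 100_000            # bp, inclusive candidate band
    max_sep: int = 1_000_000
    method: str = "t"                 # t | wilcoxon
    t_variant: str = "welch"          # welch | pooled
    fdr_max: float = 0.10             # strict
    gap_multiplier: int = 2
    summit_cf_min: float = 1.0 / 3.0  # inclusive
    singleton_cf_min: float = 1.0 / 2.0
    fdr_scope: str = "per_region"     # per_region | global
    ctrl_mode: str = "pooled"         # pooled | cell_mean
    dedup_policy: str = "mean"        # mean | first | error
    xy_nm_per_voxel: float = 1.0      # applied to x/y before ingestion
    z_nm_per_voxel: float = 1.0
    cutoff_scope: str = "pooled"      # pooled | per_region
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.neighbor_lower <= self.neighbor_upper:
            raise ValueError("need 0 < neighbor_lower <= neighbor_upper")
        if not 0 < self.min_sep <= self.max_sep:
            raise ValueError("need 0 < min_sep <= max_sep")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.method not in ("t", "wilcoxon"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.t_variant not in ("welch", "pooled"):
            raise ValueError(f"unknown t_variant {self.t_variant!r}")
        if self.fdr_scope not in ("per_region", "global"):
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")
        if self.ctrl_mode not in ("pooled", "cell_mean"):
            raise ValueError(f"unknown ctrl_mode {self.ctrl_mode!r}")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a flat key: value mapping (YAML); unknown keys are an error."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls().__dict__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def neighborhood_spec(self) -> NeighborhoodSpec:
        return NeighborhoodSpec(self.neighbor_lower, self.neighbor_upper)

    @property
    def call_config(self) -> CallConfig:
        return CallConfig(
            fdr_max=self.fdr_max,
            gap_multiplier=self.gap_multiplier,
            summit_cf_min=self.summit_cf_min,
            singleton_cf_min=self.singleton_cf_min,
        )
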