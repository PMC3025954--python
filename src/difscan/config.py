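"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Tunable thresholds and knobs of the dif prediction pipeline.

    Defaults are the operating values of the published strategy where a
    number is printed: up to 8 substitutions (no indels) in the seed
    bootstrap, a 10-bit score floor and 1e-4 E-value ceiling for profile
    hits, at least 4 complementary pairs between the XerC and XerD binding
    arms, a 0.3 protein-distance gap that separates phyla, and a 0.05 GC
    skew index below which ori/ter calls are not trusted.
    """

    max_substitutions: int = 8
    score_threshold: float = 10.0
    evalue_threshold: float = 1.0e-4
    palindrome_min: int = 4
    ori_exclusion_fraction: float = 0.10
    phylum_gap_warn: float = 0.30
    group_by: str = "genus"            # or "class"
    alternative_seed_k: int = 3
    gcsi_threshold: float = 0.05
    pseudocount: float = 0.5
    pvalue_grid: float = 1e-3          # bits per discretization step
    random_seed: int = 0
    # pairwise protein alignment scoring (identity distance)
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.max_substitutions < 0 or self.max_substitutions > 28:
            raise ValueError("max_substitutions must be in [0, 28]")
        for name in ("score_threshold", "evalue_threshold", "ori_exclusion_fraction",
                     "gcsi_threshold", "pseudocount", "pvalue_grid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.group_by not in ("genus", "class"):
            raise ValueError("group_by must be 'genus' or 'class'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
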