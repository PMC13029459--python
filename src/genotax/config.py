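"""Flat pipeline configuration with YAML round-trip.

Defaults encode the analysis conventions: 1020 bp ANI fragments, a 5 kb
junction window, at least 3 junction-spanning reads for a circular call,
a 31% missing-data ceiling, 1 kb recombination-scan windows at 5x density,
and the 94/95/97/98% ANI decision bands.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .taxonomy import DecisionThresholds


@dataclass
class PipelineConfig:
    fragment_length: int = 1020
    junction_window: int = 5_000
    min_junction_reads: int = 3
    chrom_marker_min: int = 4
    coverage_window: int = 5_000
    doubling_factor: float = 1.6
    max_missing: float = 0.31
    recomb_window: int = 1_000
    density_factor: float = 5.0
    recomb_max_iter: int = 5
    seed: int = 0
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)

    def __post_init__(self) -> None:
        for name in ("fragment_length", "junction_window",
                     "min_junction_reads", "chrom_marker_min",
                     "coverage_window", "recomb_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.max_missing <= 1.0:
            raise ValueError("max_missing must be in (0, 1]")
        if self.density_factor <= 1.0:
            raise ValueError("density_factor must exceed 1")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["thresholds"]["subspecies_band"] = list(
            data["thresholds"]["subspecies_band"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        th = data.pop("thresholds", None)
        cfg = cls(**data) if th is None else cls(
            **data,
            thresholds=DecisionThresholds(
                species_low=th["species_low"],
                species_high=th["species_high"],
                subspecies_band=tuple(th["subspecies_band"]),
                subspecies_same=th["subspecies_same"],
                ddh_species=th["ddh_species"]))
        return cfg
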