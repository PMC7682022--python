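"""Run configuration: one YAML-serializable object driving the full pipeline.

Defaults mirror the study conditions the analysis is designed around: a
combined cohort of 1447 European-like and 239 African-like individuals, a
161-SNP score with 38 typed / 123 untyped variants, six imputation replicates
per process, and a European-matched reference panel (Balding-Nichols
divergence F_ST = 0.15 for the African-like group).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ProcessConfig:
    """One imputation process to emulate."""

    name: str
    mode: str = "hmm"  # "hmm" or "parametric"
    hmm_mode: str = "sampled"  # "deterministic" or "sampled" (hmm mode only)
    r2_target: float = 0.925
    sigma_run: float = 0.1
    rho: float = 0.01
    theta: float = 0.002


@dataclass
class RunConfig:
    master_seed: int = 0
    # cohort
    populations: dict = field(default_factory=lambda: {"EUR": 1447, "AFR": 239})
    fst: dict = field(default_factory=lambda: {"EUR": 0.0, "AFR": 0.15})
    n_variants: int = 161
    maf_range: tuple = (0.01, 0.5)
    # panel / LD structure
    panel_haplotypes_per_population: int = 200
    block_length: int = 20
    block_ld: float = 0.9
    reference_population: str = "EUR"
    # score
    weight_scale: float = 0.1
    n_high_weight: int = 2
    high_weight_multiplier: float = 10.0
    fraction_typed: float = 38 / 161
    # emulation
    k: int = 6
    processes: list = field(
        default_factory=lambda: [
            ProcessConfig(name="deterministic_like", mode="hmm", hmm_mode="deterministic"),
            ProcessConfig(name="stochastic_like", mode="hmm", hmm_mode="sampled"),
        ]
    )
    # analysis
    tier_lower: float = 20.0
    tier_upper: float = 80.0
    refined_tiers: tuple = ("<5", "<10", "<15", "<20", ">80", ">85", ">90", ">95")
    range_thresholds: tuple = (1.0, 5.0, 10.0, 20.0)
    n_bins: int = 10
    rank_against: str = "self"

    def __post_init__(self) -> None:
        self.processes = [
            p if isinstance(p, ProcessConfig) else ProcessConfig(**p)
            for p in self.processes
        ]
        self.maf_range = tuple(self.maf_range)
        self.refined_tiers = tuple(self.refined_tiers)
        self.range_thresholds = tuple(float(t) for t in self.range_thresholds)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        names = [p.name for p in self.processes]
        if len(set(names)) != len(names):
            raise ValueError("process names must be unique")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["refined_tiers"] = list(self.refined_tiers)
        d["range_thresholds"] = list(self.range_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
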