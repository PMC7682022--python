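"""Core in-memory containers shared by all pipeline stages.

The pipeline carries effect-allele dosages (ALT-allele counts or expected
counts, in [0, 2]) in a samples x variants matrix, plus a variant table in
VCF coordinates (1-based positions, explicit REF/ALT).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]

#: Required columns of a PGS-Catalog-style scoring table.
SCORING_COLUMNS = [
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
]


def default_variant_table(
    n_variants: int, chrom: str = "22", start: int = 10_000, spacing: int = 1_000
) -> pd.DataFrame:
    """Build a variant table with evenly spaced, strictly increasing positions."""
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    pos = start + spacing * np.arange(n_variants, dtype=np.int64)
    return pd.DataFrame(
        {
            "id": [f"{chrom}:{p}:A:G" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )


def _check_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if variants["id"].duplicated().any():
        dups = variants.loc[variants["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate variant ids: {dups[:5]}")
    return variants.reset_index(drop=True)


@dataclass
class DosageMatrix:
    """Samples x variants matrix of effect-allele (ALT) dosages in [0, 2]."""

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = _check_variants(self.variants)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < -1e-9 or np.nanmax(self.dosages) > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column_index(self, ids) -> np.ndarray:
        """Column indices for the given variant ids; missing ids raise KeyError."""
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"variants absent from dosage matrix: {missing[:10]}")
        return np.array([lookup[v] for v in ids], dtype=np.intp)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency from mean dosage, folded at 0.5."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class HaplotypePanel:
    """Binary haplotype panel: haplotypes x variants, with population labels."""

    alleles: np.ndarray
    variants: pd.DataFrame
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.variants = _check_variants(self.variants)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.variants):
            raise ValueError("panel alleles must be (n_haplotypes, n_variants)")
        if self.alleles.size and not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("panel alleles must be binary")
        if len(self.populations) != self.alleles.shape[0]:
            raise ValueError("one population label per haplotype required")
        pos = self.variants["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("variant positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def subset_population(self, label: str) -> "HaplotypePanel":
        keep = self.populations == label
        if not keep.any():
            raise ValueError(f"population {label!r} absent from panel")
        return HaplotypePanel(self.alleles[keep], self.variants, self.populations[keep])


def merge_panels(panels: list[HaplotypePanel]) -> HaplotypePanel:
    """Stack panels that share a variant table."""
    base = panels[0]
    for p in panels[1:]:
        if not base.variants["id"].equals(p.variants["id"]):
            raise ValueError("panels must share an identical variant table")
    return HaplotypePanel(
        np.vstack([p.alleles for p in panels]),
        base.variants,
        np.concatenate([p.populations for p in panels]),
    )


@dataclass
class Cohort:
    """Diploid cohort: truth dosages, per-sample ancestry, and the underlying
    haplotypes (n_samples, 2, n_variants) used to assemble each genotype."""

    truth: DosageMatrix
    ancestry: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.ancestry = np.asarray(self.ancestry, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if len(self.ancestry) != self.truth.n_samples:
            raise ValueError("every sample needs an ancestry label")
        if self.haplotypes.shape != (self.truth.n_samples, 2, self.truth.n_variants):
            raise ValueError("haplotypes must be (n_samples, 2, n_variants)")


@dataclass
class ReplicateSet:
    """K imputed dosage matrices from one imputation process.

    Typed variants are copied from truth in every replicate; untyped dosages
    lie in [0, 2] but are otherwise process-dependent.
    """

    process: str
    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray  # (K, n_samples, n_variants)
    typed_mask: np.ndarray
    seeds: list[int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variants = _check_variants(self.variants)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.typed_mask = np.asarray(self.typed_mask, dtype=bool)
        if self.dosages.ndim != 3:
            raise ValueError("replicate dosages must be (K, n_samples, n_variants)")
        k, n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError("replicate dimensions do not match samples/variants")
        if len(self.typed_mask) != m:
            raise ValueError("typed mask length must equal variant count")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("replicate dosages must lie in [0, 2]")

    @property
    def k(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[2]

    def replicate(self, i: int) -> DosageMatrix:
        return DosageMatrix(self.samples, self.variants, self.dosages[i])


@dataclass
class PercentileFrame:
    """Per-sample WGS-based percentile and K replicate percentiles (0-100)."""

    samples: list[str]
    ancestry: np.ndarray
    wgs: np.ndarray
    replicates: np.ndarray  # (n_samples, K)

    def __post_init__(self) -> None:
        self.ancestry = np.asarray(self.ancestry, dtype=object)
        self.wgs = np.asarray(self.wgs, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=float)
        n = len(self.samples)
        if self.wgs.shape != (n,) or self.replicates.shape[0] != n:
            raise ValueError("percentile arrays must match the sample list")
        if len(self.ancestry) != n:
            raise ValueError("every sample needs an ancestry label")
        for arr in (self.wgs, self.replicates):
            if arr.size and (arr.min() < 0 or arr.max() > 100):
                raise ValueError("percentiles must lie in [0, 100]")

    @property
    def k(self) -> int:
        return self.replicates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample": self.samples, "ancestry": self.ancestry, "wgs": self.wgs}
        )
        for j in range(self.k):
            df[f"rep_{j + 1}"] = self.replicates[:, j]
        return df
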