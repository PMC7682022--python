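"""Synthetic two-population cohorts with linkage structure.

The generator emulates the statistical setting of an imputation study: an
ancestral allele-frequency spectrum, two diverged populations (a large
European-like and a smaller African-like group, Balding-Nichols divergence),
a haplotype reference panel with block-wise LD, a diploid cohort assembled
from panel haplotypes, a PRS weight model with a few dominant SNPs, and a
typed/untyped mask splitting score SNPs into directly genotyped versus
to-be-imputed sets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    Cohort,
    DosageMatrix,
    HaplotypePanel,
    SCORING_COLUMNS,
    default_variant_table,
)


@dataclass
class PopulationFrequencies:
    """Per-variant allele frequencies of one population diverged from an
    ancestral spectrum by a fixation index ``fst``."""

    label: str
    freqs: np.ndarray
    fst: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size and (self.freqs.min() < 0 or self.freqs.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")


def draw_ancestral_frequencies(
    n_variants: int, maf_range: tuple[float, float] = (0.01, 0.5), rng_seed: int = 0
) -> np.ndarray:
    """Draw ancestral allele frequencies with MAF uniform on ``maf_range``.

    The minor allele frequency is uniform on the (open-below) interval and the
    orientation (which allele is minor) is randomized, so returned frequencies
    lie in (0, 1) with folded frequency inside the range.
    """
    lo, hi = maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValueError(f"invalid MAF range ({lo}, {hi}): need 0 < lo < hi <= 0.5")
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    rng = np.random.default_rng(rng_seed)
    maf = rng.uniform(lo, hi, size=n_variants)
    flip = rng.random(n_variants) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def derive_population_frequencies(
    ancestral: np.ndarray, fst: float, rng_seed: int = 0, label: str = "POP"
) -> PopulationFrequencies:
    """Balding-Nichols draw of population frequencies around the ancestral ones.

    Each frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), i.e. mean p and variance
    F*p*(1-p). ``fst`` = 0 returns the ancestral frequencies unchanged.
    """
    p = np.asarray(ancestral, dtype=float)
    if p.size and (p.min() <= 0 or p.max() >= 1):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not (0 <= fst < 1):
        raise ValueError(f"fst must lie in [0, 1), got {fst}")
    if fst == 0:
        return PopulationFrequencies(label, p.copy(), 0.0)
    rng = np.random.default_rng(rng_seed)
    scale = (1.0 - fst) / fst
    freqs = rng.beta(p * scale, (1.0 - p) * scale)
    return PopulationFrequencies(label, freqs, fst)


def simulate_haplotype_panel(
    freqs: PopulationFrequencies,
    n_haplotypes: int,
    block_length: int,
    rng_seed: int = 0,
    block_ld: float = 0.9,
    variants: pd.DataFrame | None = None,
) -> HaplotypePanel:
    """Simulate a haplotype panel with block-wise LD via a latent block factor.

    Variants are split into consecutive blocks of ``block_length``. Each
    haplotype draws one standard-normal factor per block; the latent value at
    variant j is sqrt(block_ld) * factor + sqrt(1 - block_ld) * noise, and the
    allele is 1 when that value falls below the p_j normal quantile. Marginal
    allele frequencies therefore equal the target exactly in distribution,
    correlation (hence LD r^2) is governed by ``block_ld`` within blocks, and
    variants in different blocks are independent. ``block_length`` = 1 gives
    mutually independent variants with exact Bernoulli(p_j) margins.
    """
    p = np.asarray(freqs.freqs, dtype=float)
    m = p.size
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if not (0 <= block_ld < 1):
        raise ValueError("block_ld must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    if variants is None:
        variants = default_variant_table(m)

    n_blocks = -(-m // block_length)
    block_of = np.arange(m) // block_length
    factor = rng.standard_normal((n_haplotypes, n_blocks))
    noise = rng.standard_normal((n_haplotypes, m))
    z = np.sqrt(block_ld) * factor[:, block_of] + np.sqrt(1.0 - block_ld) * noise
    alleles = (z < stats.norm.ppf(np.clip(p, 1e-12, 1 - 1e-12))).astype(np.uint8)
    populations = np.array([freqs.label] * n_haplotypes, dtype=object)
    return HaplotypePanel(alleles, variants, populations)


def simulate_cohort(
    panel: HaplotypePanel, n_per_population: dict[str, int], rng_seed: int = 0
) -> Cohort:
    """Assemble diploid individuals by drawing two panel haplotypes each.

    Haplotypes are sampled with replacement from the requested population's
    portion of the panel; truth dosage is the ALT-allele sum, in {0, 1, 2}.
    """
    rng = np.random.default_rng(rng_seed)
    panel_pops = set(panel.populations)
    missing = [p for p in n_per_population if p not in panel_pops]
    if missing:
        raise ValueError(f"populations absent from panel: {missing}")

    hap_rows, labels, samples = [], [], []
    for pop, n in n_per_population.items():
        if n < 0:
            raise ValueError("cohort sizes must be non-negative")
        idx = np.flatnonzero(panel.populations == pop)
        draws = rng.choice(idx, size=(n, 2), replace=True)
        hap_rows.append(panel.alleles[draws])  # (n, 2, m)
        labels.extend([pop] * n)
        samples.extend(f"{pop}_{i + 1}" for i in range(n))
    haplotypes = (
        np.concatenate(hap_rows, axis=0)
        if hap_rows
        else np.empty((0, 2, panel.n_variants), dtype=np.uint8)
    )
    dosages = haplotypes.sum(axis=1).astype(float)
    truth = DosageMatrix(samples, panel.variants, dosages)
    return Cohort(truth, np.array(labels, dtype=object), haplotypes)


def generate_prs_model(
    n_variants: int | None = None,
    weight_scale: float = 0.1,
    n_high_weight: int = 2,
    high_weight_multiplier: float = 10.0,
    rng_seed: int = 0,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate a PGS-Catalog-style scoring table over the given variants.

    Weights are Normal(0, weight_scale) log odds ratios per effect-allele
    dosage; ``n_high_weight`` randomly chosen variants get their weight
    multiplied by ``high_weight_multiplier``, emulating scores dominated by a
    few large-effect loci. The effect allele is the ALT allele of each variant.
    """
    if variants is None:
        if n_variants is None:
            raise ValueError("provide n_variants or a variant table")
        variants = default_variant_table(n_variants)
    m = len(variants)
    if not (0 <= n_high_weight <= m):
        raise ValueError("n_high_weight must lie in [0, n_variants]")
    if weight_scale <= 0 or high_weight_multiplier <= 0:
        raise ValueError("weight_scale and high_weight_multiplier must be positive")
    rng = np.random.default_rng(rng_seed)
    weights = rng.normal(0.0, weight_scale, size=m)
    if n_high_weight:
        boosted = rng.choice(m, size=n_high_weight, replace=False)
        weights[boosted] *= high_weight_multiplier
    model = pd.DataFrame(
        {
            "rsID": variants["id"].to_numpy(),
            "chr_name": variants["chrom"].to_numpy(),
            "chr_position": variants["pos"].to_numpy(),
            "effect_allele": variants["alt"].to_numpy(),
            "other_allele": variants["ref"].to_numpy(),
            "effect_weight": weights,
        }
    )
    return model[SCORING_COLUMNS]


def assign_typed_mask(
    n_variants: int, fraction_typed: float, rng_seed: int = 0
) -> np.ndarray:
    """Flag a uniformly random subset of round(fraction * n) variants as typed."""
    if not (0 < fraction_typed <= 1):
        raise ValueError("fraction_typed must lie in (0, 1]")
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    n_typed = int(round(fraction_typed * n_variants))
    if n_typed == 0:
        raise ValueError(
            f"fraction_typed={fraction_typed} yields zero typed variants of {n_variants}"
        )
    rng = np.random.default_rng(rng_seed)
    mask = np.zeros(n_variants, dtype=bool)
    mask[rng.choice(n_variants, size=n_typed, replace=False)] = True
    return mask
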