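"""PRS computation, ancestry-stratified percentile ranking, and risk tiers.

The score is the standard weighted allele count, PRS_i = sum_j x_ij * beta_j,
with x_ij the effect-allele dosage in [0, 2] and beta_j the per-dosage log
odds ratio. Percentile ranks are midrank percentiles computed within each
ancestry group, so an individual's rank is relative to their matched
population, not the combined cohort.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import DosageMatrix, PercentileFrame, ReplicateSet, SCORING_COLUMNS

TIER_LABELS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class TierDefinition:
    """Two-cut quintile-style tier scheme on the percentile scale.

    Boundary convention: percentile < lower -> low; lower <= percentile <=
    upper -> intermediate; percentile > upper -> high (strict "< 20" / "> 80").
    """

    lower: float = 20.0
    upper: float = 80.0

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper < 100):
            raise ValueError("tier cut points must satisfy 0 < lower < upper < 100")


def validate_model(model: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCORING_COLUMNS if c not in model.columns]
    if missing:
        raise ValueError(f"scoring table missing columns: {missing}")
    if model["rsID"].duplicated().any():
        dups = model.loc[model["rsID"].duplicated(), "rsID"].tolist()
        raise ValueError(f"duplicate variant identifiers in scoring table: {dups[:5]}")
    weights = model["effect_weight"].to_numpy(dtype=float)
    if not np.isfinite(weights).all():
        raise ValueError("effect weights must be finite")
    same = model["effect_allele"].to_numpy() == model["other_allele"].to_numpy()
    if same.any():
        bad = model.loc[same, "rsID"].tolist()
        raise ValueError(f"effect allele equals other allele for: {bad[:5]}")
    return model


def align_model(model: pd.DataFrame, dosages: DosageMatrix):
    """Match scoring-table rows to dosage columns, resolving allele orientation.

    Returns (column indices, flip flags): where the file's effect allele is the
    matrix's REF allele the counted dosage must be flipped (x -> 2 - x).
    Variants absent from the matrix, or whose effect allele matches neither
    REF nor ALT, raise.
    """
    model = validate_model(model)
    cols = dosages.column_index(model["rsID"].to_numpy())
    ref = dosages.variants["ref"].to_numpy()[cols]
    alt = dosages.variants["alt"].to_numpy()[cols]
    eff = model["effect_allele"].to_numpy()
    flip = eff == ref
    unmatched = ~flip & (eff != alt)
    if unmatched.any():
        bad = model.loc[unmatched, "rsID"].tolist()
        raise ValueError(
            f"effect allele matches neither REF nor ALT for: {bad[:10]}; "
            "resolve orientation upstream"
        )
    return cols, flip


def compute_prs(dosages: DosageMatrix, model: pd.DataFrame) -> np.ndarray:
    """PRS_i = sum_j x_ij * beta_j over exactly the model's variants."""
    cols, flip = align_model(model, dosages)
    x = dosages.dosages[:, cols]
    if flip.any():
        x = np.where(flip[None, :], 2.0 - x, x)
    beta = model["effect_weight"].to_numpy(dtype=float)
    return x @ beta


def percentile_rank(scores: np.ndarray, ancestry: np.ndarray) -> np.ndarray:
    """Midrank percentile of each score within its ancestry group.

    percentile_i = 100 * (c_less + 0.5 * c_equal) / n, counting within the
    group; ties share the midrank, and the group mean is exactly 50.
    """
    scores = np.asarray(scores, dtype=float)
    ancestry = np.asarray(ancestry)
    if scores.ndim != 1 or len(scores) != len(ancestry):
        raise ValueError("scores and ancestry labels must align")
    if np.isnan(scores).any():
        raise ValueError("NaN scores cannot be ranked")
    out = np.empty_like(scores)
    for pop in np.unique(ancestry):
        idx = ancestry == pop
        group = scores[idx]
        out[idx] = 100.0 * (rankdata(group, method="average") - 0.5) / group.size
    return out


def percentile_against_reference(
    scores: np.ndarray, reference: np.ndarray, ancestry: np.ndarray
) -> np.ndarray:
    """Midrank percentile of each score within its group's *reference* scores."""
    scores = np.asarray(scores, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ancestry = np.asarray(ancestry)
    out = np.empty_like(scores)
    for pop in np.unique(ancestry):
        idx = ancestry == pop
        ref = np.sort(reference[idx])
        lo = np.searchsorted(ref, scores[idx], side="left")
        hi = np.searchsorted(ref, scores[idx], side="right")
        out[idx] = 100.0 * (lo + 0.5 * (hi - lo)) / ref.size
    return out


def assign_tier(
    percentiles: np.ndarray, tiers: TierDefinition = TierDefinition()
) -> np.ndarray:
    """Quintile-style tier labels: low / intermediate / high."""
    p = np.asarray(percentiles, dtype=float)
    out = np.full(p.shape, "intermediate", dtype=object)
    out[p < tiers.lower] = "low"
    out[p > tiers.upper] = "high"
    return out


def parse_onesided_tier(spec: str) -> tuple[str, float]:
    """Parse a refined one-sided tier such as "<5" or ">95"."""
    spec = spec.strip()
    if not spec or spec[0] not in "<>":
        raise ValueError(f"one-sided tier must look like '<5' or '>95', got {spec!r}")
    cut = float(spec[1:])
    if not (0 < cut < 100):
        raise ValueError(f"tier cut must lie in (0, 100), got {cut}")
    return spec[0], cut


def in_onesided_tier(percentiles: np.ndarray, spec: str) -> np.ndarray:
    direction, cut = parse_onesided_tier(spec)
    p = np.asarray(percentiles, dtype=float)
    return p < cut if direction == "<" else p > cut


def make_percentile_frame(
    truth: DosageMatrix,
    replicates: ReplicateSet,
    model: pd.DataFrame,
    ancestry: np.ndarray,
    rank_against: str = "self",
) -> PercentileFrame:
    """Score truth and every replicate, then rank within ancestry groups.

    ``rank_against='self'`` ranks each replicate's scores within that
    replicate's own distribution (default); ``'wgs'`` ranks replicate scores
    against the WGS-based score distribution instead.
    """
    if rank_against not in ("self", "wgs"):
        raise ValueError("rank_against must be 'self' or 'wgs'")
    truth_scores = compute_prs(truth, model)
    wgs_pct = percentile_rank(truth_scores, ancestry)
    rep_pct = np.empty((truth.n_samples, replicates.k))
    for i in range(replicates.k):
        scores = compute_prs(replicates.replicate(i), model)
        if rank_against == "self":
            rep_pct[:, i] = percentile_rank(scores, ancestry)
        else:
            rep_pct[:, i] = percentile_against_reference(scores, truth_scores, ancestry)
    return PercentileFrame(
        samples=truth.samples, ancestry=ancestry, wgs=wgs_pct, replicates=rep_pct
    )
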