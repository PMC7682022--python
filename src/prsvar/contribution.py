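"""Per-SNP decomposition of score variability: consistency vs impact.

Two axes locate each score SNP:

* Gini coefficient of imputation results -- for each individual, the
  normalized mean absolute difference among their K replicate dosages,
  G = sum_{a,b} |x_a - x_b| / (2 K^2 mean), averaged over individuals. 0 means
  perfectly consistent imputation; typed SNPs (copied from truth) are exactly 0.
* Percent variance explained (PVE) -- the SNP's share of total score variance,
  v_j = beta_j^2 * Var(x_j) with the empirical truth-dosage variance,
  normalized to sum to 100%.

The quadrant view separates single-SNP variability events (high PVE, moderate
Gini: dominant weights such as LPA/ANRIL-like loci) from error accumulation
across many low-weight, high-Gini SNPs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DosageMatrix, ReplicateSet
from .scoring import align_model, validate_model


def _pairwise_abs_sum(x: np.ndarray) -> np.ndarray:
    """sum_{a,b} |x_a - x_b| over the first axis (ordered pairs), vectorized.

    Uses the sorted form: sum = 2 * sum_i (2i - K + 1) * x_(i).
    """
    k = x.shape[0]
    xs = np.sort(x, axis=0)
    coef = (2 * np.arange(k) - k + 1).reshape((k,) + (1,) * (x.ndim - 1))
    return 2.0 * (coef * xs).sum(axis=0)


def snp_gini(replicates: ReplicateSet, aggregation: str = "per_individual") -> np.ndarray:
    """Per-variant Gini coefficient of replicate dosages.

    ``per_individual`` (default): the Gini of each individual's K replicate
    dosages, averaged over individuals; individuals with zero mean dosage (or
    all-equal replicates) contribute 0. ``pooled``: a single Gini over the
    pooled individual x replicate dosages per variant.
    """
    if replicates.k < 2:
        raise ValueError("at least 2 replicates are required")
    x = replicates.dosages  # (K, n, m)
    if aggregation == "per_individual":
        flat = x
    elif aggregation == "pooled":
        flat = x.reshape(x.shape[0] * x.shape[1], 1, x.shape[2])
    else:
        raise ValueError("aggregation must be 'per_individual' or 'pooled'")
    num = _pairwise_abs_sum(flat)
    mean = flat.mean(axis=0)
    total = flat.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        g = num / (2.0 * total * total * mean)
    # all-equal replicates are exactly consistent: return 0 without relying
    # on floating-point cancellation in the pairwise sum
    varies = np.ptp(flat, axis=0) > 0
    g = np.where((mean > 0) & varies, g, 0.0)
    return g.mean(axis=0) if aggregation == "per_individual" else g[0]


def percent_variance_explained(model: pd.DataFrame, truth: DosageMatrix) -> np.ndarray:
    """Each model SNP's percentage share of total score variance.

    v_j = beta_j^2 * Var(x_j) (empirical dosage variance, no HWE assumption);
    PVE_j = 100 * v_j / sum_k v_k. Degenerate scores (all v_j = 0) raise.
    """
    model = validate_model(model)
    cols, flip = align_model(model, truth)
    x = truth.dosages[:, cols]  # flipping x -> 2 - x leaves Var unchanged
    beta = model["effect_weight"].to_numpy(dtype=float)
    v = beta**2 * x.var(axis=0)
    total = v.sum()
    if total == 0:
        raise ValueError("degenerate score: every weighted dosage variance is zero")
    return 100.0 * v / total


def gini_pve_table(
    replicates: ReplicateSet,
    model: pd.DataFrame,
    truth: DosageMatrix,
    aggregation: str = "per_individual",
) -> pd.DataFrame:
    """Per-SNP table of Gini, PVE, typed flag, and weight, aligned to the model."""
    model = validate_model(model)
    gini_all = snp_gini(replicates, aggregation)
    cols, _ = align_model(model, truth)
    pve = percent_variance_explained(model, truth)
    return pd.DataFrame(
        {
            "id": model["rsID"].to_numpy(),
            "typed": replicates.typed_mask[cols],
            "weight": model["effect_weight"].to_numpy(dtype=float),
            "gini": gini_all[cols],
            "pve": pve,
        }
    )


def contribution_quadrants(
    table: pd.DataFrame, gini_cut: float = 0.1, pve_cut: float = 1.0
) -> pd.DataFrame:
    """Label each SNP high/low on both axes and name the two highlighted groups.

    "single_snp_event": high PVE with Gini above the cut (one dominant SNP
    imputed inconsistently); "error_accumulation": low PVE with high Gini
    (many small contributions fluctuating).
    """
    if not (0 < gini_cut < 1):
        raise ValueError("gini_cut must lie in (0, 1)")
    if not (0 < pve_cut < 100):
        raise ValueError("pve_cut must lie in (0, 100)")
    high_gini = table["gini"].to_numpy() > gini_cut
    high_pve = table["pve"].to_numpy() > pve_cut
    quadrant = np.where(
        high_pve,
        np.where(high_gini, "high_pve_high_gini", "high_pve_low_gini"),
        np.where(high_gini, "low_pve_high_gini", "low_pve_low_gini"),
    )
    group = np.full(len(table), "", dtype=object)
    group[high_pve & high_gini] = "single_snp_event"
    group[~high_pve & high_gini] = "error_accumulation"
    return table.assign(quadrant=quadrant, highlighted=group)
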