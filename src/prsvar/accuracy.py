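"""Imputation accuracy relative to a WGS-based gold standard.

Metrics follow the conventions of genotype-imputation concordance reporting:

* dosage R^2 -- squared Pearson correlation of imputed vs truth dosages
  (0 when either vector is constant);
* F-score -- macro-averaged F1 over the genotype classes {0, 1, 2} present in
  truth, after rounding dosages to best-guess genotypes;
* IQS -- imputation quality score: chance-adjusted genotype agreement
  (Cohen's-kappa form) on the 3x3 genotype contingency table.

Views: per-variant, per-individual (mean/min across replicates), MAF-binned,
paired process comparison (Wilcoxon signed-rank), and best-tag LD summaries.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .containers import DosageMatrix, ReplicateSet

DEFAULT_MAF_BINS = (0.0, 0.005, 0.01, 0.05, 0.1, 0.5)
GENOTYPE_CLASSES = (0, 1, 2)


def dosage_r2(imputed: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either vector is constant."""
    a = np.asarray(imputed, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("at least 2 observations required")
    ac = a - a.mean()
    bc = b - b.mean()
    den = (ac**2).sum() * (bc**2).sum()
    if den == 0:
        return 0.0
    return float((ac * bc).sum() ** 2 / den)


def _rowwise_r2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """dosage_r2 applied to matching rows of two 2-D arrays."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1) ** 2
    den = (ac**2).sum(axis=1) * (bc**2).sum(axis=1)
    return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)


def calls_from_dosage(dosages: np.ndarray) -> np.ndarray:
    """Best-guess genotype from dosage: nearest of {0, 1, 2}, ties round down."""
    return np.clip(np.ceil(np.asarray(dosages, dtype=float) - 0.5), 0, 2).astype(int)


def _check_calls(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    if calls.size and not np.isin(calls, GENOTYPE_CLASSES).all():
        raise ValueError("genotype classes must lie in {0, 1, 2}")
    return calls.astype(int)


def _contingency(imputed_calls, truth_calls) -> np.ndarray:
    imp = _check_calls(imputed_calls)
    tru = _check_calls(truth_calls)
    if imp.shape != tru.shape:
        raise ValueError("call vectors must have equal length")
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (imp, tru), 1.0)
    return table


def genotype_fscore(imputed_calls, truth_calls) -> float:
    """Macro-averaged F1 over genotype classes present in truth."""
    table = _contingency(imputed_calls, truth_calls)
    f1s = []
    for c in GENOTYPE_CLASSES:
        support = table[:, c].sum()
        if support == 0:
            continue  # class absent from truth: skipped
        tp = table[c, c]
        predicted = table[c, :].sum()
        precision = tp / predicted if predicted else 0.0
        recall = tp / support
        f1s.append(2 * precision * recall / (precision + recall) if tp else 0.0)
    return float(np.mean(f1s))


def iqs(imputed_calls, truth_calls) -> float:
    """Imputation quality score: chance-adjusted genotype agreement.

    (P_obs - P_exp) / (1 - P_exp) on the 3x3 table, where P_obs is the
    observed agreement fraction and P_exp the agreement expected from the
    marginal products. The degenerate case P_exp = 1 returns 1 when agreement
    is perfect, else 0.
    """
    table = _contingency(imputed_calls, truth_calls)
    n = table.sum()
    p_obs = np.trace(table) / n
    p_exp = float((table.sum(axis=1) * table.sum(axis=0)).sum() / n**2)
    if p_exp >= 1.0 - 1e-12:
        return 1.0 if p_obs >= 1.0 - 1e-12 else 0.0
    return float((p_obs - p_exp) / (1.0 - p_exp))


def per_variant_accuracy(
    replicates: ReplicateSet,
    truth: DosageMatrix,
    metrics=("r2", "fscore", "iqs"),
    untyped_only: bool = True,
) -> pd.DataFrame:
    """Long table of per-variant accuracy per replicate.

    By default only untyped variants are evaluated (typed variants are copied
    from truth and would trivially score perfectly).
    """
    sel = ~replicates.typed_mask if untyped_only else np.ones(truth.n_variants, bool)
    idx = np.flatnonzero(sel)
    truth_cols = truth.dosages[:, idx]
    truth_calls = calls_from_dosage(truth_cols)
    maf = truth.maf()[idx]
    rows = []
    for k in range(replicates.k):
        imp = replicates.dosages[k][:, idx]
        r2 = _rowwise_r2(imp.T, truth_cols.T) if "r2" in metrics else None
        imp_calls = calls_from_dosage(imp) if {"fscore", "iqs"} & set(metrics) else None
        for j, col in enumerate(idx):
            rec = {
                "id": replicates.variants["id"].iloc[col],
                "replicate": k,
                "typed": bool(replicates.typed_mask[col]),
                "maf": maf[j],
            }
            if "r2" in metrics:
                rec["r2"] = float(r2[j])
            if "fscore" in metrics:
                rec["fscore"] = genotype_fscore(imp_calls[:, j], truth_calls[:, j])
            if "iqs" in metrics:
                rec["iqs"] = iqs(imp_calls[:, j], truth_calls[:, j])
            rows.append(rec)
    return pd.DataFrame(rows)


def per_individual_r2_summary(
    replicates: ReplicateSet,
    truth: DosageMatrix,
    aggregate: str = "mean",
    untyped_only: bool = True,
) -> np.ndarray:
    """Per-individual R^2 across variants per replicate, aggregated over K.

    ``aggregate`` is "mean" or "min" across the K replicates, mirroring the
    population-level vs worst-run views of per-person imputation accuracy.
    """
    if aggregate not in ("mean", "min"):
        raise ValueError("aggregate must be 'mean' or 'min'")
    sel = ~replicates.typed_mask if untyped_only else np.ones(truth.n_variants, bool)
    truth_rows = truth.dosages[:, sel]
    per_rep = np.stack(
        [_rowwise_r2(replicates.dosages[k][:, sel], truth_rows) for k in range(replicates.k)]
    )  # (K, n_samples)
    return per_rep.mean(axis=0) if aggregate == "mean" else per_rep.min(axis=0)


def maf_binned_accuracy(
    replicates: ReplicateSet,
    truth: DosageMatrix,
    bins=DEFAULT_MAF_BINS,
    metrics=("r2",),
    untyped_only: bool = True,
) -> pd.DataFrame:
    """Min/median/max of per-variant metrics grouped by truth-cohort MAF bin.

    Bins are half-open (a, b]; a variant exactly on a cut point falls in the
    lower bin.
    """
    table = per_variant_accuracy(replicates, truth, metrics, untyped_only)
    edges = np.asarray(bins, dtype=float)
    labels = [f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    which = np.digitize(table["maf"].to_numpy(), edges[1:-1], right=True)
    table = table.assign(maf_bin=[labels[i] for i in which])
    rows = []
    for label in labels:
        sub = table[table["maf_bin"] == label]
        rec = {"maf_bin": label, "n": int(sub["id"].nunique())}
        for metric in metrics:
            vals = sub[metric].to_numpy()
            rec[f"{metric}_min"] = float(vals.min()) if vals.size else np.nan
            rec[f"{metric}_median"] = float(np.median(vals)) if vals.size else np.nan
            rec[f"{metric}_max"] = float(vals.max()) if vals.size else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def paired_process_comparison(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sided paired Wilcoxon signed-rank test on per-sample differences.

    Zero differences are dropped. When all differences are zero the result is
    flagged degenerate (no test possible) with p-value 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return {"statistic": np.nan, "pvalue": 1.0, "degenerate": True}
    res = wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue), "degenerate": False}


def best_tag_ld(
    dosages: DosageMatrix,
    typed_mask: np.ndarray,
    thresholds=(0.5, 0.8, 0.9),
) -> dict:
    """Best squared dosage correlation of each untyped SNP with any typed SNP.

    Returns per-untyped-SNP best r^2 and the fractions exceeding each
    threshold (non-increasing across ordered thresholds by construction).
    """
    typed_mask = np.asarray(typed_mask, dtype=bool)
    if not typed_mask.any():
        raise ValueError("at least one typed SNP is required")
    x = dosages.dosages
    typed = x[:, typed_mask]
    untyped = x[:, ~typed_mask]
    tc = typed - typed.mean(axis=0)
    uc = untyped - untyped.mean(axis=0)
    tn = np.sqrt((tc**2).sum(axis=0))
    un = np.sqrt((uc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (uc.T @ tc) / np.outer(un, tn)
    r2 = np.nan_to_num(r**2, nan=0.0)
    best = r2.max(axis=1) if typed.shape[1] else np.zeros(untyped.shape[1])
    thresholds = sorted(thresholds)
    return {
        "ids": dosages.variants.loc[~typed_mask, "id"].to_numpy(),
        "best_r2": best,
        "fractions": {t: float((best > t).mean()) for t in thresholds},
    }
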