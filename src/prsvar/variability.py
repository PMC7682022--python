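"""Per-individual percentile variability and risk-tier re-classification.

Summaries operate on a :class:`~prsvar.containers.PercentileFrame` holding the
WGS-based percentile and K replicate percentiles per individual:

* percentile range table -- counts of individuals whose replicate percentile
  range (max - min over replicates) exceeds thresholds, per ancestry stratum;
* deviation by bin -- per-individual average/maximum absolute deviation of
  replicate percentiles from the WGS percentile, summarized per WGS-percentile
  bin (box-plot statistics);
* tier re-classification -- 3x3 matrices over (individual, replicate) pairs
  and, for refined one-sided high/low-risk tiers, re-classification rates with
  untruncated Wald 95% confidence intervals.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PercentileFrame
from .scoring import (
    TIER_LABELS,
    TierDefinition,
    assign_tier,
    in_onesided_tier,
)

DEFAULT_RANGE_THRESHOLDS = (1.0, 5.0, 10.0, 20.0)
DEFAULT_REFINED_TIERS = ("<5", "<10", "<15", "<20", ">80", ">85", ">90", ">95")


def percentile_ranges(frame: PercentileFrame) -> np.ndarray:
    """Per-individual replicate percentile range, max - min over K replicates."""
    if frame.k < 2:
        raise ValueError("at least 2 replicates are needed to compute a range")
    return frame.replicates.max(axis=1) - frame.replicates.min(axis=1)


def percentile_range_table(
    frame: PercentileFrame,
    thresholds=DEFAULT_RANGE_THRESHOLDS,
) -> pd.DataFrame:
    """Counts of individuals whose percentile range exceeds each threshold.

    Rows: "<=1" (range at most the first threshold) and ">t" for each
    threshold t; columns: count and percentage per ancestry stratum plus the
    combined cohort. The "<=1" and ">1" rows partition each stratum exactly.
    """
    thresholds = sorted(float(t) for t in thresholds)
    ranges = percentile_ranges(frame)
    strata = list(dict.fromkeys(frame.ancestry)) + ["ALL"]
    rows = [f"<={thresholds[0]:g}"] + [f">{t:g}" for t in thresholds]
    records = {}
    for stratum in strata:
        sel = np.ones(len(ranges), bool) if stratum == "ALL" else frame.ancestry == stratum
        r = ranges[sel]
        n = r.size
        counts = [int((r <= thresholds[0]).sum())] + [
            int((r > t).sum()) for t in thresholds
        ]
        records[(stratum, "count")] = counts
        records[(stratum, "pct")] = [100.0 * c / n if n else np.nan for c in counts]
    out = pd.DataFrame(records, index=rows)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stratum", "measure"])
    return out


def absolute_deviations(frame: PercentileFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual (average, maximum) |replicate - WGS| percentile deviation."""
    dev = np.abs(frame.replicates - frame.wgs[:, None])
    return dev.mean(axis=1), dev.max(axis=1)


def _box_stats(values: np.ndarray) -> dict:
    if values.size == 0:
        return {k: np.nan for k in ("n", "min", "q1", "median", "q3", "max")} | {"n": 0}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
    }


def deviation_by_bin(frame: PercentileFrame, n_bins: int = 10) -> pd.DataFrame:
    """Box-plot summaries of percentile deviations per WGS-percentile bin.

    Individuals are binned by WGS percentile into ``n_bins`` equal-width bins
    on [0, 100]. Empty bins are reported with n = 0, not raised.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    avg_dev, max_dev = absolute_deviations(frame)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    which = np.clip(np.digitize(frame.wgs, edges[1:-1], right=True), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        for metric, values in (("avg_dev", avg_dev[sel]), ("max_dev", max_dev[sel])):
            rows.append(
                {"bin": b, "lo": edges[b], "hi": edges[b + 1], "metric": metric}
                | _box_stats(values)
            )
    return pd.DataFrame(rows)


def _tier_matrix(row_tiers: np.ndarray, col_tiers: np.ndarray) -> pd.DataFrame:
    n = row_tiers.size
    mat = pd.DataFrame(0.0, index=list(TIER_LABELS), columns=list(TIER_LABELS))
    for r in TIER_LABELS:
        for c in TIER_LABELS:
            mat.loc[r, c] = 100.0 * np.sum((row_tiers == r) & (col_tiers == c)) / n
    return mat


def reclassification_matrix(
    frame: PercentileFrame, tiers: TierDefinition = TierDefinition()
) -> dict:
    """Tier re-classification matrices over all (individual, replicate) pairs.

    Primary matrix: row = tier of a single replicate's percentile, column =
    tier of the individual's mean replicate percentile; cells are percentages
    of (individual, replicate) pairs. A secondary matrix with columns given by
    the WGS-based tier is emitted alongside, and the convention is recorded in
    the returned metadata.
    """
    n, k = frame.replicates.shape
    rep_tiers = assign_tier(frame.replicates.ravel(), tiers)
    mean_tiers = assign_tier(frame.replicates.mean(axis=1), tiers)
    wgs_tiers = assign_tier(frame.wgs, tiers)
    mean_cols = np.repeat(mean_tiers, k)
    wgs_cols = np.repeat(wgs_tiers, k)
    rep_rows = rep_tiers.reshape(n, k).ravel()
    return {
        "replicate_vs_mean": _tier_matrix(rep_rows, mean_cols),
        "replicate_vs_wgs": _tier_matrix(rep_rows, wgs_cols),
        "metadata": {
            "rows": "single-replicate tier",
            "columns_primary": "tier of mean replicate percentile",
            "columns_secondary": "WGS-based tier",
            "cuts": (tiers.lower, tiers.upper),
            "k": k,
            "n": n,
        },
    }


def highrisk_reclassification(
    frame: PercentileFrame,
    tier_cuts=DEFAULT_REFINED_TIERS,
    min_discordant: int = 2,
) -> pd.DataFrame:
    """Refined-tier re-classification rates with untruncated Wald 95% CIs.

    For each one-sided tier (e.g. "<5", ">95"): among individuals whose WGS
    percentile lies in the tier, the rate is the percentage for whom at least
    ``min_discordant`` replicates fall outside the tier. The CI is
    rate +/- 1.96 * sqrt(rate * (100 - rate) / m) with m the tier size, left
    untruncated. Empty tiers are reported with NaN rates.
    """
    if frame.k < 2:
        raise ValueError("at least 2 replicates are required")
    rows = []
    for spec in tier_cuts:
        member = in_onesided_tier(frame.wgs, spec)
        m = int(member.sum())
        if m == 0:
            rows.append(
                {"tier": spec, "n": 0, "n_reclassified": 0,
                 "rate": np.nan, "ci_lower": np.nan, "ci_upper": np.nan}
            )
            continue
        rep_in = in_onesided_tier(frame.replicates[member].ravel(), spec).reshape(m, -1)
        n_out = (~rep_in).sum(axis=1)
        reclassified = int((n_out >= min_discordant).sum())
        rate = 100.0 * reclassified / m
        half = 1.96 * np.sqrt(rate * (100.0 - rate) / m)
        rows.append(
            {
                "tier": spec,
                "n": m,
                "n_reclassified": reclassified,
                "rate": rate,
                "ci_lower": rate - half,
                "ci_upper": rate + half,
            }
        )
    return pd.DataFrame(rows)
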