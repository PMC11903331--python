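"""Subtype-level neojunction statistics.

Per-sample neojunction burden, between-subtype burden comparisons
(two-sided rank-sum with Benjamini-Hochberg adjustment across subtype
pairs), Pearson correlation of neojunction expression against
splicing-related gene expression with the +/-0.10 mean-correlation
classification, and differential neojunction expression between subtypes
(|log2 fold change| > 1.5 and adjusted p < 0.05).

Expression enters correlations as log2(CPM + 1) for junctions and
log2(TPM + 1) for genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class BurdenRecord:
    sample_id: str
    subtype: str
    nj_count: int


@dataclass
class CorrelationRecord:
    junction: str
    gene: str
    r_by_subtype: dict[str, Optional[float]]
    subtype_mean_r: Optional[float] = None
    cls: str = "none"


def compute_burden(calls, samples: Mapping[str, str]) -> list[BurdenRecord]:
    """Number of public neojunctions expressed per sample.

    ``samples`` maps sample id -> subtype; expression uses the per-sample
    call already attached to each neojunction's observations.
    """
    counts = {s: 0 for s in samples}
    for call in calls:
        if not call.public:
            continue
        for obs in call.tumour_observations:
            if obs.expressed and obs.sample_id in counts:
                counts[obs.sample_id] += 1
    return [
        BurdenRecord(s, samples[s], counts[s]) for s in sorted(samples)
    ]


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p; exact for groups of <= 8, else normal approx
    with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if max(len(x), len(y)) <= 8 else "asymptotic"
    try:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        )
    except ValueError:  # exact method refuses ties
        return float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
        )


def compare_burden(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests across subtype burden vectors."""
    pairs, pvals = [], []
    for a, b in combinations(sorted(groups), 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: group with <2 samples")
            continue
        pairs.append((a, b))
        pvals.append(rank_sum_p(groups[a], groups[b]))
    if not pairs:
        return pd.DataFrame(columns=["group_a", "group_b", "p_value", "p_adjusted"])
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_value": pvals,
            "p_adjusted": p_adj,
        }
    )


def correlate_nj_gene(
    nj_expression: Sequence[float], gene_expression: Sequence[float]
) -> Optional[float]:
    """Pearson correlation; None for constant or too-short vectors."""
    x = np.asarray(nj_expression, dtype=float)
    y = np.asarray(gene_expression, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def classify_correlations(
    records: Sequence[CorrelationRecord], threshold: float = 0.10
) -> list[CorrelationRecord]:
    """Mean the per-subtype correlations and classify at +/- threshold."""
    for rec in records:
        vals = [r for r in rec.r_by_subtype.values() if r is not None]
        rec.subtype_mean_r = float(np.mean(vals)) if vals else None
        if rec.subtype_mean_r is None:
            rec.cls = "none"
        elif rec.subtype_mean_r >= threshold:
            rec.cls = "positive"
        elif rec.subtype_mean_r <= -threshold:
            rec.cls = "negative"
        else:
            rec.cls = "none"
    return list(records)


def correlation_table(
    nj_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    sample_subtype: Mapping[str, str],
    threshold: float = 0.10,
    log_transform: bool = True,
) -> list[CorrelationRecord]:
    """Per-subtype Pearson correlation of every junction x gene pair.

    ``nj_expr`` (junction x sample, CPM) and ``gene_expr`` (gene x sample,
    TPM) are log2(x+1)-transformed before correlating.
    """
    if log_transform:
        nj_expr = np.log2(nj_expr + 1)
        gene_expr = np.log2(gene_expr + 1)
    subtypes: dict[str, list[str]] = {}
    for s, sub in sample_subtype.items():
        if s in nj_expr.columns and s in gene_expr.columns:
            subtypes.setdefault(sub, []).append(s)
    records = []
    for j in nj_expr.index:
        for g in gene_expr.index:
            r_by = {
                sub: correlate_nj_gene(
                    nj_expr.loc[j, cols].to_numpy(),
                    gene_expr.loc[g, cols].to_numpy(),
                )
                for sub, cols in subtypes.items()
            }
            records.append(CorrelationRecord(str(j), str(g), r_by))
    return classify_correlations(records, threshold)


def differential_nj(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    log2fc_min: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential neojunction expression between two sample groups.

    log2 fold change of group means (with pseudocount), two-sided rank-sum
    p per junction, BH adjustment; a junction is differential when
    |log2FC| > log2fc_min (strict) and adjusted p < alpha.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        warnings.warn("differential_nj: degenerate groups; empty result")
        return pd.DataFrame(
            columns=["junction", "log2fc", "p_value", "p_adjusted", "differential"]
        )
    a = expr[list(group_a)].to_numpy(dtype=float)
    b = expr[list(group_b)].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(
        b.mean(axis=1) + pseudocount
    )
    pvals = np.array([rank_sum_p(a[i], b[i]) for i in range(len(expr))])
    p_adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    return pd.DataFrame(
        {
            "junction": expr.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "differential": (np.abs(log2fc) > log2fc_min) & (p_adj < alpha),
        }
    ).reset_index(drop=True)
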