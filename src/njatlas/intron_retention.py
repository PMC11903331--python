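"""Cancer-specific intron-retention calls.

The intron-retention (IR) ratio of an intron in a sample is
``intronic_reads / (intronic_reads + spliced_reads)``.  An event is
*significant* when the tumour-normal mean difference |dIR| >= 0.10 and the
Benjamini-Hochberg adjusted two-sided rank-sum p-value is < 0.05.  A sample
is flagged *retained* when its own ratio deviates from the normal-cohort
mean by >= 0.10; the PSR of an IR event is the flagged fraction per cohort,
and cancer-specific events have tumour PSR >= 0.10 and normal PSR < 0.01.

The two-group comparison here is a rank-sum test; upstream tools fit a
generalised linear model instead, so p-values are comparable but not
identical across implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

IRKey = tuple[str, int, int, str]


@dataclass
class IREvent:
    intron: IRKey | str
    delta_ir: float
    p_value: float
    p_adjusted: float
    psr_tumour: float
    psr_normal: float
    significant: bool
    cancer_specific: bool
    tumour_ratios: np.ndarray = field(repr=False, default=None)
    normal_ratios: np.ndarray = field(repr=False, default=None)


def compute_ir_ratio(intronic_reads: float, spliced_reads: float) -> float:
    """IR ratio = intronic / (intronic + spliced); 0 when both are 0."""
    if intronic_reads < 0 or spliced_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = intronic_reads + spliced_reads
    return intronic_reads / total if total else 0.0


def ratio_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample IR ratios from a long table.

    Expects columns ``intron``, ``sample_id``, ``intronic_reads``,
    ``spliced_reads``; returns an intron x sample ratio matrix.
    """
    df = table.copy()
    df["ratio"] = [
        compute_ir_ratio(i, s)
        for i, s in zip(df.intronic_reads, df.spliced_reads)
    ]
    return df.pivot(index="intron", columns="sample_id", values="ratio")


def call_ir_events(
    tumour: pd.DataFrame,
    normal: pd.DataFrame,
    delta_min: float = 0.10,
    alpha: float = 0.05,
    psr_tumour_min: float = 0.10,
    psr_normal_max: float = 0.01,
) -> list[IREvent]:
    """Call IR events from intron x sample ratio matrices.

    Both matrices must share intron keys.  Events with fewer than two
    samples in either group are skipped with a warning.
    """
    shared = tumour.index.intersection(normal.index)
    rows = []
    for intron in shared:
        t = tumour.loc[intron].dropna().to_numpy(dtype=float)
        n = normal.loc[intron].dropna().to_numpy(dtype=float)
        if len(t) < 2 or len(n) < 2:
            warnings.warn(f"IR event {intron}: <2 samples in a group; skipped")
            continue
        if np.all(t == t[0]) and np.all(n == n[0]) and t[0] == n[0]:
            p = 1.0
        else:
            method = "exact" if max(len(t), len(n)) <= 8 else "asymptotic"
            p = float(stats.mannwhitneyu(t, n, alternative="two-sided",
                                         method=method).pvalue)
        rows.append((intron, t, n, p))
    if not rows:
        return []
    pvals = np.array([r[3] for r in rows])
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    events = []
    for (intron, t, n, p), pa in zip(rows, p_adj):
        delta = float(t.mean() - n.mean())
        normal_mean = float(n.mean())
        t_flag = np.abs(t - normal_mean) >= delta_min
        n_flag = np.abs(n - normal_mean) >= delta_min
        psr_t = float(t_flag.mean())
        psr_n = float(n_flag.mean())
        significant = abs(delta) >= delta_min and pa < alpha
        events.append(
            IREvent(
                intron=intron,
                delta_ir=delta,
                p_value=p,
                p_adjusted=float(pa),
                psr_tumour=psr_t,
                psr_normal=psr_n,
                significant=significant,
                cancer_specific=psr_t >= psr_tumour_min and psr_n < psr_normal_max,
                tumour_ratios=t,
                normal_ratios=n,
            )
        )
    return events


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intron": [e.intron for e in events],
            "delta_ir": [e.delta_ir for e in events],
            "p_value": [e.p_value for e in events],
            "p_adjusted": [e.p_adjusted for e in events],
            "psr_tumour": [e.psr_tumour for e in events],
            "psr_normal": [e.psr_normal for e in events],
            "significant": [e.significant for e in events],
            "cancer_specific": [e.cancer_specific for e in events],
        }
    )
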