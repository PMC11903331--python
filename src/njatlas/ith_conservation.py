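"""Intratumoural heterogeneity of neojunction expression.

Classifies how conserved a neojunction is across the spatially mapped
regions of one tumour: *tumour-wide* (expressed in 100% of regions),
*highly* (>70%), *moderately* (>30% to <=70%) or *weakly* (at least one
region but <=30%) conserved.  Detection in a region uses two rules:
*detectable* means junction CPM > 0 (CPM relative to the region's total
unique junction reads), *putative* means >= 10 spliced reads; tiers are
driven by the putative rule.  Also provides region-downsampling curves and
primary/metastasis (or recurrence) paired conservation fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .junction_catalog import Key

TIERS = ("absent", "weakly", "moderately", "highly", "tumour_wide")

PUTATIVE_MIN_READS = 10


@dataclass
class RegionDetection:
    junction: Key
    region_id: str
    reads: int
    cpm: float
    detectable: bool  # CPM > 0
    putative: bool  # reads >= 10


@dataclass
class ConservationCall:
    case_id: str
    junction: Key | str
    n_regions: int
    n_expressing: int
    fraction: float
    tier: str


class SingleRegionCaseError(ValueError):
    """Spatial conservation is undefined for single-region cases."""


def detect_region(
    junction: Key, region_id: str, reads: int, total_reads: int
) -> RegionDetection:
    cpm = reads / total_reads * 1e6 if total_reads else 0.0
    return RegionDetection(
        junction, region_id, reads, cpm, cpm > 0, reads >= PUTATIVE_MIN_READS
    )


def classify_conservation(
    n_expressing: int, n_regions: int, case_id: str = "", junction="",
) -> ConservationCall:
    """Map a putative-expression region count to a conservation tier."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not 0 <= n_expressing <= n_regions:
        raise ValueError("n_expressing out of range")
    fraction = n_expressing / n_regions
    if n_expressing == 0:
        tier = "absent"
    elif fraction == 1.0:
        tier = "tumour_wide"
    elif fraction > 0.7:
        tier = "highly"
    elif fraction > 0.3:
        tier = "moderately"
    else:
        tier = "weakly"
    return ConservationCall(case_id, junction, n_regions, n_expressing, fraction, tier)


def spatially_conserved(putative_flags: Sequence[bool]) -> bool:
    """Putative expression in two or more regions of the same case."""
    if len(putative_flags) < 2:
        raise SingleRegionCaseError("case has fewer than 2 regions")
    return sum(putative_flags) >= 2


def case_conservation(
    reads_by_region: Mapping[str, Mapping[Key, int]],
    junctions: Iterable[Key],
    case_id: str = "",
) -> list[ConservationCall]:
    """Conservation calls for a set of junctions across one case's regions."""
    regions = sorted(reads_by_region)
    calls = []
    for j in junctions:
        n_exp = sum(
            reads_by_region[r].get(j, 0) >= PUTATIVE_MIN_READS for r in regions
        )
        calls.append(classify_conservation(n_exp, len(regions), case_id, j))
    return calls


def putative_sets(
    reads_by_region: Mapping[str, Mapping[Key, int]],
    junctions: Iterable[Key] | None = None,
) -> dict[str, set]:
    """Per-region sets of putatively expressed junctions."""
    out = {}
    for region, reads in reads_by_region.items():
        keys = junctions if junctions is not None else reads.keys()
        out[region] = {j for j in keys if reads.get(j, 0) >= PUTATIVE_MIN_READS}
    return out


def downsample_curve(
    region_sets: Mapping[str, set],
    k_max: int,
    n_draws: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expected number of ubiquitously expressed junctions vs regions sampled.

    For k = 1..k_max, the mean over ``n_draws`` seeded draws of the number
    of junctions putatively expressed in all k sampled regions.  Draws are
    nested (each draw is a shuffled region order whose size-k subset is the
    prefix), so every draw's curve is exactly non-increasing in k.
    """
    regions = sorted(region_sets)
    if k_max > len(regions):
        raise ValueError(f"k_max {k_max} exceeds region count {len(regions)}")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_draws, k_max))
    for d in range(n_draws):
        order = rng.permutation(regions)
        running: set | None = None
        for k in range(1, k_max + 1):
            s = region_sets[order[k - 1]]
            running = set(s) if running is None else running & s
            counts[d, k - 1] = len(running)
    return counts.mean(axis=0)


def paired_conservation(set_primary: set, set_secondary: set) -> float:
    """Fraction of primary-tumour junctions persisting in the paired sample."""
    if not set_primary:
        raise ValueError("primary junction set is empty")
    return len(set_primary & set_secondary) / len(set_primary)


def conservation_to_frame(calls: Sequence[ConservationCall]) -> pd.DataFrame:
    from .io import key_to_str

    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in calls],
            "junction": [
                key_to_str(c.junction) if isinstance(c.junction, tuple) else c.junction
                for c in calls
            ],
            "n_regions": [c.n_regions for c in calls],
            "n_expressing": [c.n_expressing for c in calls],
            "fraction": [c.fraction for c in calls],
            "tier": [c.tier for c in calls],
        }
    )
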