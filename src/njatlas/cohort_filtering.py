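"""Cohort-level gates and neojunction calls.

Implements the sample and junction gates used to call *public* (recurrent)
and *cancer-specific* neojunctions from tumour and normal cohorts:

* tumour samples are retained at tumour purity >= 0.60 (normals always);
* coding, non-mitochondrial transcripts are retained at median TPM >= 10
  in at least one subtype;
* a sample *expresses* a junction when it has >= 10 target spliced reads,
  >= 20 total (target + canonical) spliced reads, and a spliced frequency
  target / (target + canonical) >= 1%;
* the positive sample rate (PSR) is the fraction of gated cohort samples
  expressing the junction; public <=> tumour PSR >= 10%; cancer-specific
  <=> normal PSR < 1%.

All thresholds live in :class:`ThresholdConfig` and are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .junction_catalog import (
    AnnotationIndex,
    CanonicalAssignment,
    Key,
    SpliceTypeCall,
    TranscriptModel,
)

MITO_CHROMS = {"chrM", "MT", "chrMT", "M"}


class PipelineError(RuntimeError):
    """A gate left nothing to analyse."""


@dataclass
class ThresholdConfig:
    """All cohort-filtering thresholds, with the published defaults."""

    count_min: int = 10  # min target spliced reads per sample
    depth_min: int = 20  # min target+canonical spliced reads per sample
    freq_min: float = 0.01  # min spliced frequency
    freq_inclusive: bool = True  # >= (main-text reading) vs > (methods reading)
    psr_public_min: float = 0.10
    psr_normal_max: float = 0.01
    purity_min: float = 0.60
    tpm_min: float = 10.0


@dataclass
class CohortSample:
    sample_id: str
    cohort_label: str  # 'tumour' | 'normal'
    tumour_purity: Optional[float] = None
    subtype: str = ""
    total_junction_reads: int = 0


@dataclass
class FrequencyObservation:
    junction: Key
    sample_id: str
    target_reads: int
    canonical_reads: int
    frequency: float
    expressed: bool


@dataclass
class NeojunctionCall:
    junction: Key
    splice: SpliceTypeCall
    canonical: CanonicalAssignment
    psr_tumour: float
    psr_normal: float
    public: bool
    cancer_specific: bool
    tumour_observations: list[FrequencyObservation] = field(default_factory=list)
    normal_observations: list[FrequencyObservation] = field(default_factory=list)


# ---------------------------------------------------------------------------


def gate_samples(
    samples: Iterable[CohortSample], config: ThresholdConfig = ThresholdConfig()
) -> list[CohortSample]:
    """Purity gate: tumour samples need purity >= purity_min; normals pass."""
    retained = []
    for s in samples:
        if s.cohort_label == "normal":
            retained.append(s)
        elif s.tumour_purity is None:
            warnings.warn(f"tumour sample {s.sample_id} lacks purity; dropped")
        elif s.tumour_purity >= config.purity_min:
            retained.append(s)
    if not any(s.cohort_label == "tumour" for s in retained):
        raise PipelineError("no tumour samples pass the purity gate")
    return retained


def gate_transcripts(
    transcripts: Iterable[TranscriptModel],
    expression: pd.DataFrame,
    sample_subtype: Mapping[str, str],
    config: ThresholdConfig = ThresholdConfig(),
) -> list[TranscriptModel]:
    """Expression gate for coding, non-mitochondrial transcripts.

    ``expression`` is a transcript x sample TPM matrix.  A transcript is
    retained when its median TPM reaches ``tpm_min`` in at least one
    subtype; the per-subtype medians are stored on the model.
    """
    subtype_cols: dict[str, list[str]] = {}
    for sample, subtype in sample_subtype.items():
        if sample in expression.columns:
            subtype_cols.setdefault(subtype, []).append(sample)
    retained = []
    for tx in transcripts:
        if not tx.coding or tx.chrom in MITO_CHROMS:
            continue
        if tx.transcript_id not in expression.index:
            warnings.warn(f"{tx.transcript_id} missing from expression matrix")
            continue
        row = expression.loc[tx.transcript_id]
        medians = {
            sub: float(row[cols].median()) for sub, cols in subtype_cols.items()
        }
        tx.median_tpm_by_subtype = medians
        if any(m >= config.tpm_min for m in medians.values()):
            retained.append(tx)
    return retained


def compute_frequency(target_reads: int, canonical_reads: int) -> float:
    """Spliced frequency: target / (target + canonical); 0 when both are 0."""
    if target_reads < 0 or canonical_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = target_reads + canonical_reads
    return target_reads / total if total else 0.0


def sample_expresses(
    obs: FrequencyObservation, config: ThresholdConfig = ThresholdConfig()
) -> bool:
    """Per-sample expression call: count, depth and frequency gates."""
    depth = obs.target_reads + obs.canonical_reads
    if obs.target_reads < config.count_min or depth < config.depth_min:
        return False
    if config.freq_inclusive:
        return obs.frequency >= config.freq_min
    return obs.frequency > config.freq_min


def make_observation(
    junction: Key,
    sample_id: str,
    target_reads: int,
    canonical_reads: int,
    config: ThresholdConfig = ThresholdConfig(),
) -> FrequencyObservation:
    obs = FrequencyObservation(
        junction,
        sample_id,
        target_reads,
        canonical_reads,
        compute_frequency(target_reads, canonical_reads),
        False,
    )
    obs.expressed = sample_expresses(obs, config)
    return obs


def compute_psr(observations: Sequence[FrequencyObservation], n_gated: int) -> float:
    """Positive sample rate: expressing samples over gated cohort size."""
    if n_gated <= 0:
        raise PipelineError("empty cohort after gating")
    return sum(o.expressed for o in observations) / n_gated


def call_neojunctions(
    tumour_reads: Mapping[str, Mapping[Key, int]],
    normal_reads: Mapping[str, Mapping[Key, int]],
    catalogue: Mapping[Key, tuple[SpliceTypeCall, CanonicalAssignment]],
    config: ThresholdConfig = ThresholdConfig(),
) -> list[NeojunctionCall]:
    """Cohort statistics and public / cancer-specific flags per junction.

    ``tumour_reads`` / ``normal_reads`` map sample id -> {junction key ->
    unique reads} for gated samples.  A cohort-sum pre-filter (total target
    reads >= count_min and total depth >= depth_min over the tumour cohort)
    is applied before per-sample evaluation.
    """
    n_t, n_n = len(tumour_reads), len(normal_reads)
    if n_t == 0:
        raise PipelineError("empty tumour cohort")
    calls = []
    for key, (splice, canon) in catalogue.items():
        ckey = canon.canonical

        def observe(reads_by_sample):
            obs = []
            for sample, reads in reads_by_sample.items():
                target = reads.get(key, 0)
                canonical = reads.get(ckey, 0) if ckey else 0
                obs.append(make_observation(key, sample, target, canonical, config))
            return obs

        t_obs = observe(tumour_reads)
        cohort_target = sum(o.target_reads for o in t_obs)
        cohort_depth = sum(o.target_reads + o.canonical_reads for o in t_obs)
        if cohort_target < config.count_min or cohort_depth < config.depth_min:
            continue
        n_obs = observe(normal_reads)
        psr_t = compute_psr(t_obs, n_t)
        psr_n = compute_psr(n_obs, n_n) if n_n else 0.0
        calls.append(
            NeojunctionCall(
                junction=key,
                splice=splice,
                canonical=canon,
                psr_tumour=psr_t,
                psr_normal=psr_n,
                public=psr_t >= config.psr_public_min,
                cancer_specific=psr_n < config.psr_normal_max,
                tumour_observations=t_obs,
                normal_observations=n_obs,
            )
        )
    calls.sort(key=lambda c: (-c.psr_tumour, c.junction))
    return calls


# ---------------------------------------------------------------------------
# end-to-end discovery


def _reads_by_sample(records_by_sample, keys=None):
    out = {}
    for sample, records in records_by_sample.items():
        out[sample] = {r.key: r.unique_reads for r in records}
    return out


def discover(
    records_by_sample: Mapping[str, list],
    metadata: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    expression: pd.DataFrame,
    config: ThresholdConfig = ThresholdConfig(),
    exclude_multi_region: bool = True,
) -> tuple[list[NeojunctionCall], AnnotationIndex]:
    """Run the discovery pipeline: gates, catalogue, cohort calls.

    ``records_by_sample`` maps sample id to parsed junction records.  Samples
    belonging to multi-region cases (more than one region per case) are by
    default excluded from the cohort PSR denominators; they feed the
    intratumoural-heterogeneity analysis instead.
    """
    from .junction_catalog import build_annotation_index, catalogue_junctions

    samples = [
        CohortSample(
            row.sample_id,
            row.cohort,
            None if pd.isna(getattr(row, "purity", None)) else float(row.purity),
            getattr(row, "subtype", "") or "",
        )
        for row in metadata.itertuples()
    ]
    if exclude_multi_region and {"case_id", "region_id"} <= set(metadata.columns):
        region_counts = metadata.groupby("case_id")["region_id"].nunique()
        multi = set(metadata[metadata.case_id.map(region_counts).gt(1)].sample_id)
        samples = [s for s in samples if s.sample_id not in multi]
    gated = gate_samples(samples, config)
    sample_subtype = {s.sample_id: s.subtype for s in gated}
    kept_tx = gate_transcripts(transcripts, expression, sample_subtype, config)
    index = build_annotation_index(kept_tx)

    tumour_ids = [s.sample_id for s in gated if s.cohort_label == "tumour"]
    normal_ids = [s.sample_id for s in gated if s.cohort_label == "normal"]
    reads = _reads_by_sample(
        {s: records_by_sample[s] for s in tumour_ids + normal_ids if s in records_by_sample}
    )
    tumour_reads = {s: reads.get(s, {}) for s in tumour_ids}
    normal_reads = {s: reads.get(s, {}) for s in normal_ids}

    cohort_counts: dict[Key, int] = {}
    for s in tumour_ids:
        for key, n in tumour_reads.get(s, {}).items():
            cohort_counts[key] = cohort_counts.get(key, 0) + n

    tumour_records = [
        r for s in tumour_ids for r in records_by_sample.get(s, [])
    ]
    catalogue = catalogue_junctions(tumour_records, index, cohort_counts)

    # strand-resolved keys: re-key the read maps so unknown-strand records
    # observed in samples match the catalogue keys
    def rekey(reads_map):
        out = {}
        for sample, rm in reads_map.items():
            new = dict(rm)
            for (chrom, s_, e_, strand), n in rm.items():
                if strand == "?":
                    for st in "+-":
                        k2 = (chrom, s_, e_, st)
                        if k2 in catalogue or index.is_annotated(chrom, s_, e_, st):
                            new[k2] = new.get(k2, 0) + n
            out[sample] = new
        return out

    calls = call_neojunctions(rekey(tumour_reads), rekey(normal_reads), catalogue, config)
    return calls, index


def calls_to_frame(calls: Sequence[NeojunctionCall]) -> pd.DataFrame:
    from .io import key_to_str

    rows = []
    for c in calls:
        rows.append(
            {
                "junction": key_to_str(c.junction),
                "gene_id": c.splice.gene_id or "",
                "splice_type": c.splice.splice_type,
                "nt_delta": c.splice.nt_delta,
                "frame_status": c.splice.frame_status,
                "psr_tumour": c.psr_tumour,
                "psr_normal": c.psr_normal,
                "public": c.public,
                "cancer_specific": c.cancer_specific,
            }
        )
    return pd.DataFrame(rows)


def frequency_matrix(calls: Sequence[NeojunctionCall]) -> pd.DataFrame:
    """Per-sample spliced-frequency matrix (junctions x samples)."""
    from .io import key_to_str

    data: dict[str, dict[str, float]] = {}
    for c in calls:
        row = {}
        for o in c.tumour_observations + c.normal_observations:
            row[o.sample_id] = o.frequency
        data[key_to_str(c.junction)] = row
    return pd.DataFrame(data).T.fillna(0.0).sort_index()
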