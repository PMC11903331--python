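"""Seeded synthetic references and cohorts with planted ground truth.

Generates everything the pipeline consumes without any downloads: a genome
with multi-exon protein-coding genes (GT..AG splice motifs at intron
boundaries), the matching GTF annotation and reference proteome, tumour and
normal cohorts of STAR-dialect junction tables with planted non-annotated
junctions at controlled per-sample spliced frequencies and cohort positive
sample rates, multi-region cases with controlled clonality, purity
metadata, TPM expression matrices, surrogate two-scorer HLA-presentation
tables, and intron-retention count tables.  Every output is a deterministic
function of the seed; a machine-readable truth table records, for each
planted junction, its realized coordinates, splice type, frame status,
expressing samples and the cohort flags they imply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as njio
from .cohort_filtering import ThresholdConfig, make_observation
from .ith_conservation import classify_conservation
from .junction_catalog import (
    Key,
    TranscriptModel,
    build_annotation_index,
    assign_canonical,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
STOPS = ["TAA", "TAG", "TGA"]
_COMP = str.maketrans("ACGT", "TGCA")

LOSS_TYPES = {"A3_loss", "A5_loss", "exon_skip", "in_exon"}
GAIN_TYPES = {"A3_gain", "A5_gain", "in_intron"}


class ConfigurationError(ValueError):
    pass


@dataclass
class PlantSpec:
    """One junction to plant: where, what kind, and how prevalent."""

    gene_id: str
    splice_type: str
    nt_delta: int
    target_tumour_psr: float = 0.5
    target_frequency: float = 0.05
    clonality: str = "tumour_wide"  # 'tumour_wide' | 'subclonal'
    subclonal_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.splice_type in LOSS_TYPES and self.nt_delta >= 0:
            raise ConfigurationError(
                f"{self.splice_type} requires negative nt_delta"
            )
        if self.splice_type in GAIN_TYPES and self.nt_delta <= 0:
            raise ConfigurationError(
                f"{self.splice_type} requires positive nt_delta"
            )
        for frac in (self.target_tumour_psr, self.target_frequency):
            if not 0 <= frac <= 1:
                raise ConfigurationError("target fractions must lie in [0, 1]")
        if self.clonality not in ("tumour_wide", "subclonal"):
            raise ConfigurationError(f"unknown clonality {self.clonality!r}")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 10
    n_tumour_samples: int = 20
    n_normal_samples: int = 50
    n_cases: int = 0
    regions_per_case: int = 5
    planted_junctions: list[PlantSpec] = field(default_factory=list)
    purity_distribution: tuple[float, float] = (0.85, 0.05)
    normal_leak_rate: float = 0.0
    read_depth_scale: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tumour_samples", "n_normal_samples"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_cases < 0 or (self.n_cases and self.regions_per_case < 1):
            raise ConfigurationError("invalid multi-region case counts")
        if not 0 <= self.normal_leak_rate <= 1:
            raise ConfigurationError("normal_leak_rate must lie in [0, 1]")


@dataclass
class Reference:
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    proteome: dict[str, str]
    gene_protein: dict[str, str]


@dataclass
class SimulatedCohort:
    reference: Reference
    tables: dict[str, dict[Key, int]]  # sample -> junction -> unique reads
    metadata: pd.DataFrame
    expression: pd.DataFrame
    truth: dict[str, dict]
    annotated: set[Key]


# ---------------------------------------------------------------------------
# reference generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        CODONS[aa][rng.integers(0, len(CODONS[aa]))] for aa in protein
    )


def generate_reference(config: SimulationConfig) -> Reference:
    """Multi-exon protein-coding genes on a single synthetic chromosome.

    Each gene has 3-6 exons, a CDS that translates without internal stops,
    short UTRs, and GT..AG (strand-appropriate) motifs at intron
    boundaries.  Genes alternate strand; the proteome holds every reference
    CDS translation.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 1  # next genomic coordinate to fill (1-based)
    transcripts: list[TranscriptModel] = []
    proteome: dict[str, str] = {}
    gene_protein: dict[str, str] = {}

    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        plen = int(rng.integers(110, 190))
        protein = "M" + "".join(
            np.array(list(AMINO_ACIDS))[rng.integers(0, 20, plen - 1)]
        )
        cds = _backtranslate(protein, rng) + STOPS[rng.integers(0, 3)]
        utr5 = _random_seq(rng, int(rng.integers(30, 60)))
        utr3 = _random_seq(rng, int(rng.integers(30, 60)))
        mrna = utr5 + cds + utr3
        n_exons = int(rng.integers(3, 7))
        # split the mRNA into n_exons chunks, each >= 60 nt
        min_chunk = 60
        free = len(mrna) - n_exons * min_chunk
        cuts = np.sort(rng.integers(0, free + 1, n_exons - 1))
        sizes = []
        prev = 0
        for j, c in enumerate(list(cuts) + [free]):
            sizes.append(min_chunk + int(c - prev))
            prev = c
        chunks, pos = [], 0
        for size in sizes:
            chunks.append(mrna[pos : pos + size])
            pos += size
        intron_lens = rng.integers(90, 300, n_exons - 1)

        # genomic layout: leftmost exon first; for '-' genes the first
        # transcript chunk is the rightmost genomic exon
        genomic_chunks = chunks if strand == "+" else [
            c.translate(_COMP)[::-1] for c in chunks[::-1]
        ]
        gap = _random_seq(rng, int(rng.integers(300, 800)))
        pieces.append(gap)
        cursor += len(gap)
        exons: list[tuple[int, int]] = []
        for j, chunk in enumerate(genomic_chunks):
            start = cursor
            pieces.append(chunk)
            cursor += len(chunk)
            exons.append((start, cursor - 1))
            if j < len(genomic_chunks) - 1:
                ilen = int(intron_lens[j if strand == "+" else n_exons - 2 - j])
                iseq = _random_seq(rng, ilen)
                if strand == "+":
                    iseq = "GT" + iseq[2:-2] + "AG"
                else:
                    iseq = "CT" + iseq[2:-2] + "AC"
                pieces.append(iseq)
                cursor += ilen

        # genomic CDS span from transcript coordinates of the CDS
        def genomic_of(tpos: int) -> int:
            # tpos: 0-based transcript coordinate
            if strand == "-":
                tpos = len(mrna) - 1 - tpos
                # now tpos indexes the genomic-left-to-right concatenation
            off = tpos
            for s, e in exons:
                if off <= e - s:
                    return s + off
                off -= e - s + 1
            raise AssertionError("transcript coordinate out of range")

        c0, c1 = len(utr5), len(utr5) + len(cds) - 1
        g0, g1 = genomic_of(c0), genomic_of(c1)
        cds_span = (min(g0, g1), max(g0, g1))
        tx = TranscriptModel(
            f"{gene_id}.t1", gene_id, chrom, strand, exons, cds_span
        )
        transcripts.append(tx)
        proteome[f"{gene_id}_ref"] = protein
        gene_protein[gene_id] = protein

    tail = _random_seq(rng, 500)
    pieces.append(tail)
    genome = {chrom: "".join(pieces)}
    return Reference(transcripts, genome, proteome, gene_protein)


# ---------------------------------------------------------------------------
# junction planting


def planted_junction_key(
    spec: PlantSpec, tx: TranscriptModel
) -> tuple[Key, int]:
    """Realize a PlantSpec as genomic junction coordinates.

    Returns the junction key and the realized nt_delta (for exon skips the
    realized value is minus the skipped exon's length; for intron-internal
    junctions it is the retained intronic length).
    """
    introns = tx.introns
    exons = tx.exons
    strand = tx.strand
    d = abs(spec.nt_delta)
    mid = len(introns) // 2
    iv = introns[mid]

    if spec.splice_type in ("A3_loss", "A3_gain", "A5_loss", "A5_gain"):
        loss = spec.splice_type.endswith("loss")
        three_prime = spec.splice_type.startswith("A3")
        # on '+', the acceptor (3') is the right end of the intron
        right_end = three_prime if strand == "+" else not three_prime
        s, e = iv
        if right_end:
            flank = exons[mid + 1]
            if loss and d >= flank[1] - flank[0]:
                raise ConfigurationError("nt_delta exceeds flanking exon")
            if not loss and d >= e - s:
                raise ConfigurationError("nt_delta exceeds intron")
            e = e + d if loss else e - d
        else:
            flank = exons[mid]
            if loss and d >= flank[1] - flank[0]:
                raise ConfigurationError("nt_delta exceeds flanking exon")
            if not loss and d >= e - s:
                raise ConfigurationError("nt_delta exceeds intron")
            s = s - d if loss else s + d
        return (tx.chrom, s, e, strand), spec.nt_delta

    if spec.splice_type == "exon_skip":
        e_idx = max(1, min(len(exons) - 2, mid))
        key = (tx.chrom, introns[e_idx - 1][0], introns[e_idx][1], strand)
        skipped = exons[e_idx]
        return key, -(skipped[1] - skipped[0] + 1)

    if spec.splice_type == "in_exon":
        ex = exons[max(1, min(len(exons) - 2, mid))]
        if ex[1] - ex[0] - 1 < d:
            raise ConfigurationError("in_exon nt_delta exceeds exon interior")
        js = ex[0] + max(1, (ex[1] - ex[0] + 1 - d) // 2)
        return (tx.chrom, js, js + d - 1, strand), spec.nt_delta

    if spec.splice_type == "in_intron":
        ilen = iv[1] - iv[0] + 1
        jlen = ilen - d
        if d < 2 or jlen < 1:
            raise ConfigurationError("in_intron nt_delta infeasible for intron")
        left = max(1, d // 2)
        js = iv[0] + left
        return (tx.chrom, js, js + jlen - 1, strand), spec.nt_delta

    raise ConfigurationError(f"unknown splice_type {spec.splice_type!r}")


# ---------------------------------------------------------------------------
# cohort emission


def _sample_ids(config: SimulationConfig):
    tumour = [f"T{i + 1:03d}" for i in range(config.n_tumour_samples)]
    normal = [f"N{i + 1:03d}" for i in range(config.n_normal_samples)]
    regions = {
        f"C{c + 1:02d}": [
            f"C{c + 1:02d}_R{r + 1:02d}" for r in range(config.regions_per_case)
        ]
        for c in range(config.n_cases)
    }
    return tumour, normal, regions


def plant_and_emit_cohort(
    config: SimulationConfig,
    reference: Reference,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> SimulatedCohort:
    """Junction tables, metadata, expression and truth for one cohort.

    Every sample's table carries Poisson-distributed reads for all
    annotated introns; planted junctions appear in the designated
    expressing samples with read counts that realize the target spliced
    frequency and are clamped to satisfy the per-sample count and depth
    gates, so planted truth is unambiguous.  Expressing tumour samples are
    a seeded shuffled prefix of ceil(PSR x n) gated samples; each normal
    sample leaks each planted junction with probability
    ``normal_leak_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tx_by_gene = {t.gene_id: t for t in reference.transcripts}
    for spec in config.planted_junctions:
        if spec.gene_id not in tx_by_gene:
            raise ConfigurationError(f"unknown gene {spec.gene_id}")

    index = build_annotation_index(reference.transcripts)
    annotated: list[Key] = sorted(index.annotated_introns)
    tumour_ids, normal_ids, region_ids = _sample_ids(config)
    all_samples = (
        tumour_ids + normal_ids + [s for rs in region_ids.values() for s in rs]
    )

    # purity and metadata
    mu, sd = config.purity_distribution
    purities = np.clip(rng.normal(mu, sd, len(all_samples)), 0.0, 1.0)
    meta_rows = []
    for i, s in enumerate(all_samples):
        is_normal = s in set(normal_ids)
        case = s.split("_")[0] if "_" in s else s
        region = s.split("_")[1] if "_" in s else "R01"
        meta_rows.append(
            {
                "sample_id": s,
                "cohort": "normal" if is_normal else "tumour",
                "purity": "" if is_normal else round(float(purities[i]), 4),
                "subtype": "normal" if is_normal else ("subA" if i % 2 else "subB"),
                "case_id": case,
                "region_id": region,
            }
        )
    metadata = pd.DataFrame(meta_rows)
    gated_tumour = [
        r["sample_id"]
        for r in meta_rows
        if r["cohort"] == "tumour"
        and r["sample_id"] in tumour_ids
        and float(r["purity"]) >= thresholds.purity_min
    ]
    if not gated_tumour:
        raise ConfigurationError("purity distribution leaves no gated tumour samples")

    # background: annotated intron reads per sample
    tables: dict[str, dict[Key, int]] = {}
    for s in all_samples:
        reads = rng.poisson(config.read_depth_scale, len(annotated))
        tables[s] = dict(zip(annotated, (int(x) for x in reads)))

    # planted junctions
    truth: dict[str, dict] = {}
    for spec in config.planted_junctions:
        tx = tx_by_gene[spec.gene_id]
        key, realized_delta = planted_junction_key(spec, tx)
        if key in index.annotated_introns:
            raise ConfigurationError(f"planted junction {key} is annotated")
        canon = assign_canonical(key, index).canonical

        n_expr = math.ceil(spec.target_tumour_psr * len(gated_tumour))
        order = list(rng.permutation(gated_tumour))
        expressing_t = sorted(order[:n_expr])
        leak = rng.random(len(normal_ids)) < config.normal_leak_rate
        expressing_n = sorted(np.array(normal_ids)[leak].tolist())
        expressing_regions: dict[str, list[str]] = {}
        for case, regions in region_ids.items():
            if spec.clonality == "tumour_wide":
                chosen = list(regions)
            else:
                k = math.ceil(spec.subclonal_fraction * len(regions))
                chosen = sorted(rng.permutation(regions)[:k].tolist())
            expressing_regions[case] = chosen

        f = spec.target_frequency
        for s in expressing_t + expressing_n + [
            r for rs in expressing_regions.values() for r in rs
        ]:
            c = tables[s].get(canon, 0) if canon else 0
            target = max(
                thresholds.count_min,
                thresholds.depth_min - c,
                math.ceil(f / (1 - f) * c) if f < 1 else c * 100,
            )
            tables[s][key] = target

        # frame truth from realized delta and CDS overlap
        cs, ce = tx.cds_span
        in_cds = key[1] <= ce and key[2] >= cs
        if not in_cds:
            frame = "noncoding"
        else:
            frame = "in_frame" if realized_delta % 3 == 0 else "frameshift"

        # cohort flags implied by the emitted counts
        def expressed(sample: str) -> bool:
            c = tables[sample].get(canon, 0) if canon else 0
            return make_observation(
                key, sample, tables[sample].get(key, 0), c, thresholds
            ).expressed

        psr_t = sum(expressed(s) for s in gated_tumour) / len(gated_tumour)
        psr_n = (
            sum(expressed(s) for s in normal_ids) / len(normal_ids)
            if normal_ids
            else 0.0
        )
        tiers = {
            case: classify_conservation(
                len(expressing_regions[case]), len(regions)
            ).tier
            for case, regions in region_ids.items()
        }
        truth[njio.key_to_str(key)] = {
            "gene_id": spec.gene_id,
            "splice_type": spec.splice_type,
            "nt_delta": realized_delta,
            "frame_status": frame,
            "expressing_tumour_samples": expressing_t,
            "expressing_normal_samples": expressing_n,
            "expressing_regions": expressing_regions,
            "expected_public": psr_t >= thresholds.psr_public_min,
            "expected_cancer_specific": psr_n < thresholds.psr_normal_max,
            "expected_tier": tiers,
            "psr_tumour": psr_t,
            "psr_normal": psr_n,
        }

    # expression matrix: all transcripts comfortably above the TPM gate
    tpm = rng.lognormal(np.log(50.0), 0.4, (len(reference.transcripts), len(all_samples)))
    expression = pd.DataFrame(
        np.round(tpm, 3),
        index=[t.transcript_id for t in reference.transcripts],
        columns=all_samples,
    )
    return SimulatedCohort(
        reference, tables, metadata, expression, truth, set(annotated)
    )


def simulate(config: SimulationConfig) -> SimulatedCohort:
    return plant_and_emit_cohort(config, generate_reference(config))


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the full synthetic dataset (reference, tables, truth) to disk."""
    outdir = Path(outdir)
    (outdir / "junctions").mkdir(parents=True, exist_ok=True)
    njio.write_fasta(cohort.reference.genome, outdir / "genome.fa")
    njio.write_fasta(cohort.reference.proteome, outdir / "proteome.fa")
    njio.write_gtf(cohort.reference.transcripts, outdir / "annotation.gtf")
    for sample, reads in cohort.tables.items():
        rows = [
            (key, n, key in cohort.annotated)
            for key, n in sorted(reads.items())
            if n > 0
        ]
        njio.write_sj_tab(rows, outdir / "junctions" / f"{sample}.SJ.out.tab")
    njio.write_metadata(cohort.metadata, outdir / "metadata.tsv")
    njio.write_expression(cohort.expression, outdir / "expression.tsv")
    njio.write_truth(cohort.truth, outdir / "truth.json")


def worked_example_a3_loss(seed: int = 0) -> tuple[TranscriptModel, dict, Key]:
    """A coding transcript with a codon-aligned in-frame A3 loss of 6 nt.

    Exon 2 begins on a codon boundary, so extending intron 1 six bases into
    exon 2 deletes exactly two consecutive amino acids from the product --
    the classic in-frame acceptor-site loss.  Returns (transcript, genome,
    junction key).
    """
    rng = np.random.default_rng(seed)
    protein = "M" + "".join(
        np.array(list(AMINO_ACIDS))[rng.integers(0, 20, 98)]
    )  # 99 residues; 33 encoded by exon 1
    cds = _backtranslate(protein, rng) + "TAA"  # 300 nt
    exons = [(101, 199), (301, 400), (501, 601)]  # chunks 99 + 100 + 101 nt
    chunks = [cds[:99], cds[99:199], cds[199:300]]
    contig = list(_random_seq(rng, 800))
    for (s, e), chunk in zip(exons, chunks):
        contig[s - 1 : e] = list(chunk)
    # splice motifs at annotated intron boundaries
    for s, e in [(200, 300), (401, 500)]:
        contig[s - 1 : s + 1] = list("GT")
        contig[e - 2 : e] = list("AG")
    genome = {"chrW": "".join(contig)}
    tx = TranscriptModel("WEX.t1", "WEX", "chrW", "+", exons, cds_span=(101, 601))
    junction: Key = ("chrW", 200, 306, "+")  # A3 loss of exon-2 bases 301-306
    return tx, genome, junction


# ---------------------------------------------------------------------------
# surrogate presentation-score tables


def generate_score_tables(
    candidates: Sequence[str],
    planted_binders: set[str],
    seed: int,
    alleles: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two deterministic scorer tables with planted double-top binders.

    Planted binders receive the highest scores from both scorers; the
    remaining candidates are ordered oppositely by the two scorers, so a
    non-planted peptide ranked highly by one scorer sits at the bottom of
    the other and the top-percentile intersection recovers exactly the
    planted set.
    """
    from .neoantigen_pipeline import DEFAULT_ALLELES

    alleles = list(alleles) if alleles is not None else list(DEFAULT_ALLELES)
    uniq = list(dict.fromkeys(candidates))
    if not uniq:
        raise ConfigurationError("candidates must be non-empty")
    missing = set(planted_binders) - set(uniq)
    if missing:
        raise ConfigurationError(f"planted binders not in candidates: {missing}")
    rng = np.random.default_rng(seed)
    planted = sorted(planted_binders)
    others = [c for c in uniq if c not in planted_binders]
    others = list(rng.permutation(others)) if others else []

    score_a = {p: 1000.0 - i for i, p in enumerate(planted)}
    score_b = dict(score_a)
    for i, p in enumerate(others):
        score_a[p] = 500.0 - i
        score_b[p] = 500.0 - (len(others) - 1 - i)

    def table(scores: Mapping[str, float]) -> pd.DataFrame:
        rows = [
            {"peptide": p, "allele": al, "score": scores[p]}
            for al in alleles
            for p in uniq
        ]
        return pd.DataFrame(rows)

    return table(score_a), table(score_b)


# ---------------------------------------------------------------------------
# intron-retention count tables


def simulate_ir_tables(
    seed: int,
    n_introns: int = 50,
    n_retained: int = 5,
    n_tumour: int = 20,
    n_normal: int = 20,
    tumour_ratio: float = 0.4,
    normal_ratio: float = 0.02,
    depth: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Long-format intronic/spliced count tables with planted retention.

    Planted introns retain at ~``tumour_ratio`` in tumours and
    ~``normal_ratio`` in normals; background introns sit at the normal
    ratio in both groups.  Returns (tumour table, normal table, planted
    intron ids).
    """
    rng = np.random.default_rng(seed)
    introns = [f"intron_{i + 1:03d}" for i in range(n_introns)]
    planted = set(introns[:n_retained])

    def rows(samples: list[str], retained_ratio: float) -> pd.DataFrame:
        recs = []
        for intron in introns:
            ratio = retained_ratio if intron in planted else normal_ratio
            for s in samples:
                intronic = int(rng.poisson(ratio * depth))
                spliced = int(rng.poisson((1 - ratio) * depth))
                recs.append(
                    {
                        "intron": intron,
                        "sample_id": s,
                        "intronic_reads": intronic,
                        "spliced_reads": spliced,
                    }
                )
        return pd.DataFrame(recs)

    tumour = rows([f"T{i + 1:03d}" for i in range(n_tumour)], tumour_ratio)
    normal = rows([f"N{i + 1:03d}" for i in range(n_normal)], normal_ratio)
    return tumour, normal, planted


# ---------------------------------------------------------------------------
# YAML config


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    plants = [PlantSpec(**p) for p in raw.pop("planted_junctions", [])]
    if "purity_distribution" in raw:
        raw["purity_distribution"] = tuple(raw["purity_distribution"])
    return SimulationConfig(planted_junctions=plants, **raw)


def default_plant_specs(
    reference: Reference,
    n: int,
    rng: np.random.Generator,
    psr_range: tuple[float, float] = (0.2, 0.9),
    frequency: float = 0.05,
) -> list[PlantSpec]:
    """A mixed bag of plant specs across genes, types and strands.

    Frequencies and PSRs default to at least twice the calling thresholds
    so planted truth is recoverable without ambiguity.
    """
    types = ["A3_loss", "A3_gain", "A5_loss", "A5_gain", "exon_skip",
             "in_exon", "in_intron"]
    genes = [t.gene_id for t in reference.transcripts]
    if n > len(genes):
        raise ConfigurationError("need at least one gene per planted junction")
    specs = []
    for i in range(n):
        st = types[i % len(types)]
        mag = int(rng.integers(2, 30))
        if st == "in_intron":
            mag = max(mag, 2)
        delta = -mag if st in LOSS_TYPES else mag
        specs.append(
            PlantSpec(
                gene_id=genes[i],
                splice_type=st,
                nt_delta=delta,
                target_tumour_psr=float(rng.uniform(*psr_range)),
                target_frequency=frequency,
                clonality="tumour_wide" if i % 2 == 0 else "subclonal",
                subclonal_fraction=0.5,
            )
        )
    return specs
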