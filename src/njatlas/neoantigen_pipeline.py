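"""From neojunctions to HLA-presented neoantigen candidates.

Reconstructs the mutant transcript implied by a neojunction, re-extracts the
CDS from the annotated start codon, translates it (stopping at the first
stop codon, with frameshift tails translated in the new frame), tiles all
8-11-mer peptides overlapping the junction-affected residues with up to
30-residue flanking context, removes peptides present in the reference
proteome, and intersects top-percentile calls from two pluggable
HLA-presentation scorers across a panel of HLA class I alleles.  Detected
mass-spectrometry peptides can be mapped back to junctions to mark them
MS-confirmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .junction_catalog import (
    AnnotationIndex,
    Key,
    TranscriptModel,
    apply_junction,
    total_length,
)

#: the five most prevalent HLA-A alleles, covering most of the global population
DEFAULT_ALLELES = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-A*03:01",
    "HLA-A*11:01",
    "HLA-A*24:02",
)

DEFAULT_K_RANGE = (8, 9, 10, 11)
FLANK_LEN = 30


@dataclass
class MutantTranscript:
    transcript_id: str
    junction: Key
    mutant_cds: str
    reference_protein: str
    mutant_protein: str
    junction_residue_span: Optional[tuple[int, int]]  # 1-based inclusive
    frameshift: bool
    premature_stop: bool
    noncoding: bool = False


@dataclass
class PeptideCandidate:
    sequence: str
    junction: Key
    position: int  # 1-based start in mutant protein
    flank_n: str
    flank_c: str
    tumour_specific: Optional[bool] = None
    percentile_rank: dict[tuple[str, str], float] = field(default_factory=dict)
    selected: bool = False


# ---------------------------------------------------------------------------
# sequence plumbing


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_sequence(
    genome: Mapping[str, str], chrom: str, exons: Sequence[tuple[int, int]], strand: str
) -> str:
    contig = genome[chrom]
    seq = "".join(contig[s - 1 : e] for s, e in exons)
    return _revcomp(seq) if strand == "-" else seq


def _transcript_coord(
    exons: Sequence[tuple[int, int]], strand: str, genomic_pos: int
) -> Optional[int]:
    """0-based position of a genomic base in the spliced transcript, or None."""
    offset = 0
    for s, e in exons:
        if s <= genomic_pos <= e:
            offset += genomic_pos - s
            break
        offset += e - s + 1
    else:
        return None
    if strand == "-":
        return total_length(exons) - 1 - offset
    return offset


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate to the first stop codon; returns (protein, stop_found)."""
    usable = cds[: len(cds) - len(cds) % 3]
    protein = str(Seq(usable).translate())
    stop = protein.find("*")
    if stop >= 0:
        return protein[:stop], True
    return protein, False


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


# ---------------------------------------------------------------------------
# mutant transcript construction


def build_mutant_transcript(
    transcript: TranscriptModel,
    junction: Key,
    genome: Mapping[str, str],
) -> MutantTranscript:
    """Apply a neojunction to a coding transcript and translate the result.

    The junction's interval becomes intronic; annotated introns it overlaps
    are restored to exonic status first (splice-site shifts into an intron
    and intron-internal junctions retain intronic sequence).  The CDS is
    re-extracted from the annotated start codon; if the start codon itself
    is spliced out the product is flagged noncoding and yields no peptides.
    """
    if not transcript.coding:
        raise ValueError(f"{transcript.transcript_id} has no CDS")
    chrom, js, je, _ = junction
    mut_exons = apply_junction(transcript, js, je)
    strand = transcript.strand
    cs, ce = transcript.cds_span
    start_pos = cs if strand == "+" else ce

    ref_seq = spliced_sequence(genome, chrom, transcript.exons, strand)
    mut_seq = spliced_sequence(genome, chrom, mut_exons, strand)
    ref_start = _transcript_coord(transcript.exons, strand, start_pos)
    mut_start = _transcript_coord(mut_exons, strand, start_pos)
    if mut_start is None or ref_start is None:
        return MutantTranscript(
            transcript.transcript_id, junction, "", "", "", None,
            frameshift=False, premature_stop=False, noncoding=True,
        )
    ref_cds = ref_seq[ref_start:]
    mut_cds = mut_seq[mut_start:]
    ref_protein, _ = translate_cds(ref_cds)
    mut_protein, stop_found = translate_cds(mut_cds)
    if not stop_found:
        warnings.warn(
            f"{transcript.transcript_id} x {junction}: no in-frame stop before "
            "transcript end; product truncated at transcript end"
        )

    nt_delta = len(mut_seq) - len(ref_seq)
    frameshift = abs(nt_delta) % 3 != 0

    a = _common_prefix_len(ref_cds, mut_cds)
    if frameshift:
        lo_nt, hi_nt = a, max(len(mut_cds) - 1, a)
    else:
        b = _common_suffix_len(ref_cds[a:], mut_cds[a:])
        lo_nt, hi_nt = a, len(mut_cds) - b - 1
        if hi_nt < lo_nt:  # pure deletion: span the two flanking residues
            lo_nt, hi_nt = max(a - 1, 0), min(a, max(len(mut_cds) - 1, 0))
    first = lo_nt // 3 + 1
    last = min(hi_nt // 3 + 1, len(mut_protein))
    span = (first, last) if first <= len(mut_protein) and mut_protein else None

    return MutantTranscript(
        transcript_id=transcript.transcript_id,
        junction=junction,
        mutant_cds=mut_cds[: 3 * len(mut_protein) + (3 if stop_found else 0)],
        reference_protein=ref_protein,
        mutant_protein=mut_protein,
        junction_residue_span=span,
        frameshift=frameshift,
        premature_stop=stop_found and len(mut_protein) < len(ref_protein),
        noncoding=not mut_protein,
    )


# ---------------------------------------------------------------------------
# peptide tiling and filtering


def tile_peptides(
    mutant: MutantTranscript,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    flank_len: int = FLANK_LEN,
) -> list[PeptideCandidate]:
    """All 8-11-mers overlapping the junction-affected residues.

    Windows are deduplicated by sequence (first occurrence kept) and carry
    up to ``flank_len`` residues of flanking context on each side.  Windows
    containing an ambiguous residue ``X`` are disqualified.
    """
    protein = mutant.mutant_protein
    span = mutant.junction_residue_span
    if span is None or not protein:
        warnings.warn(f"{mutant.junction}: no junction-affected residues; no tiles")
        return []
    first, last = span
    out: list[PeptideCandidate] = []
    seen: set[str] = set()
    for k in sorted(k_range):
        if len(protein) < k:
            continue
        lo = max(1, first - k + 1)
        hi = min(last, len(protein) - k + 1)
        for i in range(lo, hi + 1):  # 1-based window start
            seq = protein[i - 1 : i - 1 + k]
            if "X" in seq or seq in seen:
                continue
            seen.add(seq)
            out.append(
                PeptideCandidate(
                    sequence=seq,
                    junction=mutant.junction,
                    position=i,
                    flank_n=protein[max(0, i - 1 - flank_len) : i - 1],
                    flank_c=protein[i - 1 + k : i - 1 + k + flank_len],
                )
            )
    return out


def filter_tumour_specific(
    candidates: Sequence[PeptideCandidate], proteome: Mapping[str, str]
) -> list[PeptideCandidate]:
    """Flag candidates absent from the reference proteome as tumour-specific."""
    if not proteome:
        raise ValueError("reference proteome is empty")
    blob = "|".join(s.upper() for s in proteome.values())
    for c in candidates:
        c.tumour_specific = c.sequence.upper() not in blob
    return list(candidates)


# ---------------------------------------------------------------------------
# presentation-scorer intersection


def read_score_table(path) -> pd.DataFrame:
    """Score TSV with columns peptide, allele, score (higher = better)."""
    return pd.read_csv(path, sep="\t")


def _percentile_ranks(scores: pd.Series, higher_is_better: bool = True) -> pd.Series:
    """Competition percentile rank; ties share the better (smaller) rank."""
    n = len(scores)
    ranks = scores.rank(method="min", ascending=not higher_is_better)
    return ranks / n


def select_presented(
    candidates: Sequence[PeptideCandidate],
    score_table_a: pd.DataFrame,
    score_table_b: pd.DataFrame,
    alleles: Sequence[str] = DEFAULT_ALLELES,
    q: float = 0.01,
    higher_is_better: tuple[bool, bool] = (True, True),
) -> list[PeptideCandidate]:
    """Intersect top-percentile calls from two scorers.

    Percentile ranks are computed per allele within the tumour-specific
    candidate set for each scorer; a candidate is selected when some allele
    ranks it in the top ``q`` fraction with *both* scorers.
    """
    specific = [c for c in candidates if c.tumour_specific]
    peptides = [c.sequence for c in specific]
    pepset = set(peptides)
    for name, table, hib in (
        ("A", score_table_a, higher_is_better[0]),
        ("B", score_table_b, higher_is_better[1]),
    ):
        for allele in alleles:
            sub = table[(table.allele == allele) & table.peptide.isin(pepset)]
            sub = sub.drop_duplicates("peptide").set_index("peptide")
            missing = pepset - set(sub.index)
            if missing:
                raise KeyError(
                    f"scorer {name}, allele {allele}: missing peptides "
                    f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
                )
            ranks = _percentile_ranks(sub.score, hib)
            for c in specific:
                c.percentile_rank[(name, allele)] = float(ranks[c.sequence])
    for c in candidates:
        c.selected = False
    for c in specific:
        c.selected = any(
            c.percentile_rank[("A", al)] <= q and c.percentile_rank[("B", al)] <= q
            for al in alleles
        )
    return list(candidates)


def map_to_nej(candidates: Sequence[PeptideCandidate]) -> dict[Key, int]:
    """Distinct parent junctions of selected candidates, with counts."""
    out: dict[Key, int] = {}
    for c in candidates:
        if c.selected:
            out[c.junction] = out.get(c.junction, 0) + 1
    return out


def match_ms_peptides(
    detected_peptides: Iterable[str],
    mutants: Sequence[MutantTranscript],
    proteome: Mapping[str, str],
) -> set[Key]:
    """Junctions whose mutant protein contains a detected MS peptide.

    A junction is MS-confirmed when a detected peptide matches its mutant
    protein at a position overlapping the junction-affected residues and is
    absent from the reference proteome.
    """
    blob = "|".join(s.upper() for s in proteome.values())
    confirmed: set[Key] = set()
    for mut in mutants:
        if mut.junction_residue_span is None:
            continue
        first, last = mut.junction_residue_span
        protein = mut.mutant_protein
        for pep in detected_peptides:
            pep = pep.strip().upper()
            if not pep or pep in blob:
                continue
            start = protein.find(pep)
            while start >= 0:
                # residue window [start+1, start+len] vs span [first, last]
                if start + 1 <= last and start + len(pep) >= first:
                    confirmed.add(mut.junction)
                    break
                start = protein.find(pep, start + 1)
    return confirmed


# ---------------------------------------------------------------------------
# convenience pipeline


def candidates_for_calls(
    calls,
    index: AnnotationIndex,
    genome: Mapping[str, str],
    proteome: Mapping[str, str],
    k_range: Iterable[int] = DEFAULT_K_RANGE,
) -> tuple[list[MutantTranscript], list[PeptideCandidate]]:
    """Mutant transcripts and tumour-specific-flagged tiles for coding calls.

    Junctions classified ``other`` or with a noncoding frame status are
    excluded: peptide calls require unambiguous transcript provenance.
    """
    tx_by_id = {
        t.transcript_id: t for g in index.genes.values() for t in g.transcripts
    }
    mutants, tiles = [], []
    for call in calls:
        sp = call.splice
        if sp.splice_type == "other" or sp.frame_status == "noncoding":
            continue
        tx = tx_by_id.get(sp.affected_transcript_id)
        if tx is None:
            continue
        mut = build_mutant_transcript(tx, call.junction, genome)
        if mut.noncoding:
            continue
        mutants.append(mut)
        tiles.extend(tile_peptides(mut, k_range))
    if tiles:
        filter_tumour_specific(tiles, proteome)
    return mutants, tiles


def candidates_to_frame(candidates: Sequence[PeptideCandidate]) -> pd.DataFrame:
    from .io import key_to_str

    return pd.DataFrame(
        {
            "sequence": [c.sequence for c in candidates],
            "junction": [key_to_str(c.junction) for c in candidates],
            "position": [c.position for c in candidates],
            "flank_n": [c.flank_n for c in candidates],
            "flank_c": [c.flank_c for c in candidates],
            "tumour_specific": [c.tumour_specific for c in candidates],
            "selected": [c.selected for c in candidates],
        }
    )
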