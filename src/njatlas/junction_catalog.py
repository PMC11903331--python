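"""Splice-junction catalogue: parsing, annotation indexing, and classification.

A *neojunction* is a splice junction observed in RNA-seq that is absent from
the reference transcript annotation.  This module parses per-sample junction
tables in the STAR ``SJ.out.tab`` dialect, indexes a transcript annotation,
decides annotated vs non-annotated status, classifies each non-annotated
junction by splice type (alternative 3'/5' splice-site loss or gain, exon
skip, junction-in-exon, junction-in-intron) and reading-frame consequence,
and assigns each neojunction the annotated *canonical* junction used as the
denominator partner for spliced-frequency statistics.

Coordinates are 1-based inclusive intron coordinates throughout (the STAR
convention): ``intron_start`` is the first intronic base, ``intron_end`` the
last.  5' (donor) and 3' (acceptor) are oriented by transcription strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

#: junction / intron identity: (chrom, intron_start, intron_end, strand)
Key = tuple[str, int, int, str]

STRAND_CODES = {"0": "?", "1": "+", "2": "-"}

SPLICE_TYPES = (
    "A3_loss",
    "A3_gain",
    "A5_loss",
    "A5_gain",
    "exon_skip",
    "in_exon",
    "in_intron",
    "other",
)


class ParseError(ValueError):
    """A malformed junction-table row."""


@dataclass
class JunctionRecord:
    """One observed splice junction in one sample."""

    chrom: str
    intron_start: int  # 1-based first intronic base
    intron_end: int  # 1-based last intronic base
    strand: str  # '+', '-' or '?'
    unique_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be non-negative")

    @property
    def key(self) -> Key:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


@dataclass
class TranscriptModel:
    """Gene/transcript structure with exons, CDS span and expression summary."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping
    cds_span: Optional[tuple[int, int]] = None
    median_tpm_by_subtype: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def coding(self) -> bool:
        return self.cds_span is not None

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def max_median_tpm(self) -> float:
        return max(self.median_tpm_by_subtype.values(), default=0.0)


@dataclass
class SpliceTypeCall:
    splice_type: str
    nt_delta: Optional[int]  # exonic nt removed < 0, intronic nt gained > 0
    frame_status: str  # 'in_frame' | 'frameshift' | 'noncoding'
    affected_transcript_id: Optional[str]
    gene_id: Optional[str] = None


@dataclass
class CanonicalAssignment:
    junction: Key
    canonical: Optional[Key]
    shared_site: str  # 'donor' | 'acceptor' | 'none'


# ---------------------------------------------------------------------------
# SJ.out.tab parsing


def parse_junction_table(path, sample_id: str) -> list[JunctionRecord]:
    """Parse a 9-column STAR ``SJ.out.tab`` file into :class:`JunctionRecord`s.

    Columns: chrom, intron first base, intron last base, strand code
    {0: unknown, 1: +, 2: -}, motif code, annotated flag, unique reads,
    multimapping reads, max overhang.  Rows with zero unique reads are
    retained; callers apply read filters.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = STRAND_CODES[fields[3]]
                unique = int(fields[6])
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(
                JunctionRecord(chrom, start, end, strand, unique, sample_id)
            )
    return records


# ---------------------------------------------------------------------------
# interval arithmetic (1-based inclusive)


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, merging adjacent ones."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_interval(
    ivs: Sequence[tuple[int, int]], cut: tuple[int, int]
) -> list[tuple[int, int]]:
    """Remove ``cut`` from a sorted disjoint interval list."""
    cs, ce = cut
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < cs or s > ce:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs - 1))
        if e > ce:
            out.append((ce + 1, e))
    return out


def total_length(ivs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in ivs)


def apply_junction(
    transcript: TranscriptModel, intron_start: int, intron_end: int
) -> list[tuple[int, int]]:
    """Exon structure of the transcript after splicing the given junction.

    The new intron removes everything it covers; annotated introns of the
    transcript that overlap it are first restored to exonic status, so that
    splice-site shifts into an intron (A3/A5 gain) and junctions internal to
    an intron correctly retain the flanking intronic sequence as exonic.
    """
    base = list(transcript.exons)
    for s, e in transcript.introns:
        if s <= intron_end and e >= intron_start:
            base.append((s, e))
    return subtract_interval(merge_intervals(base), (intron_start, intron_end))


def nt_delta_for_junction(
    transcript: TranscriptModel, intron_start: int, intron_end: int
) -> int:
    """Signed change in spliced-transcript length caused by the junction."""
    mutant = apply_junction(transcript, intron_start, intron_end)
    return total_length(mutant) - total_length(transcript.exons)


# ---------------------------------------------------------------------------
# annotation index


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: list[TranscriptModel]

    @property
    def intron_set(self) -> set[tuple[int, int]]:
        introns: set[tuple[int, int]] = set()
        for tx in self.transcripts:
            introns.update(tx.introns)
        return introns

    @property
    def intron_starts(self) -> set[int]:
        return {s for s, _ in self.intron_set}

    @property
    def intron_ends(self) -> set[int]:
        return {e for _, e in self.intron_set}


class AnnotationIndex:
    """Queries over a transcript annotation.

    Answers: is a (chrom, start, end, strand) an annotated intron; which genes
    overlap an interval; donor/acceptor site sets per gene; which transcript
    represents a gene (the coding transcript with the highest median TPM).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.genes: dict[str, GeneModel] = {}
        by_gene: dict[str, list[TranscriptModel]] = {}
        for tx in transcripts:
            by_gene.setdefault(tx.gene_id, []).append(tx)
        self._trees: dict[str, IntervalTree] = {}
        self.annotated_introns: set[Key] = set()
        for gene_id, txs in by_gene.items():
            chrom, strand = txs[0].chrom, txs[0].strand
            span = (min(t.span[0] for t in txs), max(t.span[1] for t in txs))
            gene = GeneModel(gene_id, chrom, strand, span, txs)
            self.genes[gene_id] = gene
            tree = self._trees.setdefault(chrom, IntervalTree())
            tree[span[0] : span[1] + 1] = gene_id
            for tx in txs:
                for s, e in tx.introns:
                    self.annotated_introns.add((chrom, s, e, strand))

    def is_annotated(self, chrom: str, start: int, end: int, strand: str = "?") -> bool:
        if strand == "?":
            return any(
                (chrom, start, end, st) in self.annotated_introns for st in "+-"
            )
        return (chrom, start, end, strand) in self.annotated_introns

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: str = "?"
    ) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end + 1)]
        if strand in "+-":
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: g.gene_id)

    def representative_transcript(self, gene: GeneModel) -> TranscriptModel:
        coding = [t for t in gene.transcripts if t.coding]
        pool = coding or gene.transcripts
        return max(pool, key=lambda t: (t.max_median_tpm, t.transcript_id))


def build_annotation_index(transcripts: Iterable[TranscriptModel]) -> AnnotationIndex:
    return AnnotationIndex(transcripts)


# ---------------------------------------------------------------------------
# classification


def _containing(ivs: Sequence[tuple[int, int]], pos: int) -> Optional[int]:
    for i, (s, e) in enumerate(ivs):
        if s <= pos <= e:
            return i
    return None


def _other(gene_id: Optional[str] = None) -> SpliceTypeCall:
    return SpliceTypeCall("other", None, "noncoding", None, gene_id)


def classify_splice_type(
    junction: JunctionRecord | Key, index: AnnotationIndex
) -> SpliceTypeCall:
    """Classify a non-annotated junction against the annotation.

    Precedence: (1) both splice sites annotated for the gene and at least one
    full exon strictly inside the junction => exon skip; (2) exactly one site
    annotated => A3/A5 gain or loss depending on which side deviates and
    whether the deviant intron end lies in an exon (loss of exonic sequence)
    or an intron (gain of intronic sequence); (3) both ends inside one exon
    => in_exon; (4) both ends inside one intron => in_intron; (5) other.
    Junctions overlapping zero or more than one gene are ``other``.
    """
    if isinstance(junction, JunctionRecord):
        chrom, js, je, strand = junction.key
    else:
        chrom, js, je, strand = junction

    genes = index.genes_overlapping(chrom, js, je, strand)
    if len(genes) != 1:
        return _other()
    gene = genes[0]
    tx = index.representative_transcript(gene)

    left_annot = js in gene.intron_starts
    right_annot = je in gene.intron_ends

    splice_type: Optional[str] = None
    if left_annot and right_annot:
        skipped = any(s > js and e < je for s, e in tx.exons)
        if skipped:
            splice_type = "exon_skip"
    if splice_type is None and left_annot != right_annot:
        deviant = je if left_annot else js
        # donor is the transcription-5' side of the intron
        deviant_is_left = not left_annot
        donor_side = deviant_is_left if gene.strand == "+" else not deviant_is_left
        prime = "A5" if donor_side else "A3"
        if _containing(tx.exons, deviant) is not None:
            splice_type = f"{prime}_loss"
        elif _containing(tx.introns, deviant) is not None:
            splice_type = f"{prime}_gain"
    if splice_type is None:
        ei, ej = _containing(tx.exons, js), _containing(tx.exons, je)
        ii, ij = _containing(tx.introns, js), _containing(tx.introns, je)
        if ei is not None and ei == ej and not (left_annot or right_annot):
            splice_type = "in_exon"
        elif ii is not None and ii == ij and not (left_annot or right_annot):
            splice_type = "in_intron"
    if splice_type is None:
        return _other(gene.gene_id)

    delta = nt_delta_for_junction(tx, js, je)
    if tx.coding and tx.cds_span is not None:
        cs, ce = tx.cds_span
        in_cds = js <= ce and je >= cs
    else:
        in_cds = False
    if not in_cds:
        frame = "noncoding"
    elif abs(delta) % 3 == 0:
        frame = "in_frame"
    else:
        frame = "frameshift"
    return SpliceTypeCall(splice_type, delta, frame, tx.transcript_id, gene.gene_id)


def assign_canonical(
    junction: JunctionRecord | Key,
    index: AnnotationIndex,
    cohort_counts: Mapping[Key, int] | None = None,
) -> CanonicalAssignment:
    """Pick the annotated partner junction used as frequency denominator.

    Preference order: annotated intron of the same gene sharing the donor
    site; then sharing the acceptor site; several candidates are broken by
    highest summed tumour-cohort read count, then shortest intron.  Junctions
    sharing no site (in_exon / in_intron) take the annotated intron fully
    containing them, else the nearest-overlapping one, else none.
    """
    if isinstance(junction, JunctionRecord):
        chrom, js, je, strand = junction.key
    else:
        chrom, js, je, strand = junction
    cohort_counts = cohort_counts or {}

    genes = index.genes_overlapping(chrom, js, je, strand)
    key: Key = (chrom, js, je, strand)
    if len(genes) != 1:
        return CanonicalAssignment(key, None, "none")
    gene = genes[0]
    introns = sorted(gene.intron_set)

    def pick(cands: list[tuple[int, int]]) -> Key:
        best = max(
            cands,
            key=lambda iv: (
                cohort_counts.get((chrom, iv[0], iv[1], gene.strand), 0),
                -(iv[1] - iv[0]),
            ),
        )
        return (chrom, best[0], best[1], gene.strand)

    donor_left = gene.strand == "+"
    same_donor = [iv for iv in introns if (iv[0] == js if donor_left else iv[1] == je)]
    if same_donor:
        return CanonicalAssignment(key, pick(same_donor), "donor")
    same_acceptor = [
        iv for iv in introns if (iv[1] == je if donor_left else iv[0] == js)
    ]
    if same_acceptor:
        return CanonicalAssignment(key, pick(same_acceptor), "acceptor")

    containing = [iv for iv in introns if iv[0] <= js and iv[1] >= je]
    if containing:
        return CanonicalAssignment(key, pick(containing), "none")
    overlapping = [iv for iv in introns if iv[0] <= je and iv[1] >= js]
    if overlapping:
        best = max(
            overlapping,
            key=lambda iv: (
                min(iv[1], je) - max(iv[0], js),
                -(iv[1] - iv[0]),
                -iv[0],
            ),
        )
        return CanonicalAssignment(
            key, (chrom, best[0], best[1], gene.strand), "none"
        )
    return CanonicalAssignment(key, None, "none")


def catalogue_junctions(
    records: Iterable[JunctionRecord],
    index: AnnotationIndex,
    cohort_counts: Mapping[Key, int] | None = None,
) -> dict[Key, tuple[SpliceTypeCall, CanonicalAssignment]]:
    """Classify every distinct non-annotated junction seen in ``records``.

    Junctions with unknown strand inherit the strand of the unique
    overlapping gene; junctions that stay unresolvable are catalogued as
    ``other`` and carry no canonical partner.
    """
    out: dict[Key, tuple[SpliceTypeCall, CanonicalAssignment]] = {}
    seen: set[Key] = set()
    for rec in records:
        key = rec.key
        if key in seen:
            continue
        seen.add(key)
        chrom, js, je, strand = key
        if strand == "?":
            genes = index.genes_overlapping(chrom, js, je)
            if len(genes) == 1:
                strand = genes[0].strand
                key = (chrom, js, je, strand)
        if index.is_annotated(chrom, js, je, strand):
            continue
        if key in out:
            continue
        call = classify_splice_type(key, index)
        canon = assign_canonical(key, index, cohort_counts)
        out[key] = (call, canon)
    return out


def write_catalogue(catalogue, path) -> None:
    """Write the junction catalogue as TSV."""
    import pandas as pd

    rows = []
    for key, (call, canon) in sorted(catalogue.items()):
        rows.append(
            {
                "chrom": key[0],
                "intron_start": key[1],
                "intron_end": key[2],
                "strand": key[3],
                "gene_id": call.gene_id or "",
                "splice_type": call.splice_type,
                "nt_delta": "" if call.nt_delta is None else call.nt_delta,
                "frame_status": call.frame_status,
                "canonical": (
                    "{}:{}-{}:{}".format(*canon.canonical) if canon.canonical else ""
                ),
                "shared_site": canon.shared_site,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
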