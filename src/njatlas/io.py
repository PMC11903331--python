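"""Readers and writers for the pipeline's file formats.

GTF here means the Ensembl-style dialect: 1-based inclusive coordinates,
``gene``/``transcript``/``exon``/``CDS`` features, and ``gene_id`` /
``transcript_id`` attributes.  FASTA goes through Biopython.  Junction
tables use the STAR ``SJ.out.tab`` 9-column dialect (see
:mod:`njatlas.junction_catalog` for the reader).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junction_catalog import Key, TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models (exons + CDS span) from a GTF file."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            ad = dict(_ATTR_RE.findall(attrs))
            tx = ad["transcript_id"]
            meta[tx] = (ad["gene_id"], chrom, strand)
            target = exons if feature == "exon" else cds
            target.setdefault(tx, []).append((int(start), int(end)))
    out = []
    for tx, (gene, chrom, strand) in meta.items():
        spans = cds.get(tx)
        cds_span = (min(s for s, _ in spans), max(e for _, e in spans)) if spans else None
        out.append(TranscriptModel(tx, gene, chrom, strand, exons.get(tx, []), cds_span))
    return sorted(out, key=lambda t: (t.chrom, t.span, t.transcript_id))


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            s, e = tx.span
            for feature, fs, fe in [("transcript", s, e)] + [
                ("exon", es, ee) for es, ee in tx.exons
            ]:
                fh.write(
                    f"{tx.chrom}\tnjatlas\t{feature}\t{fs}\t{fe}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds_span:
                cs, ce = tx.cds_span
                for es, ee in tx.exons:
                    os_, oe = max(es, cs), min(ee, ce)
                    if os_ <= oe:
                        fh.write(
                            f"{tx.chrom}\tnjatlas\tCDS\t{os_}\t{oe}\t.\t{tx.strand}\t0\t{attrs}\n"
                        )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


_SJ_STRAND = {"?": 0, "+": 1, "-": 2}


def write_sj_tab(
    rows: Iterable[tuple[Key, int, bool]], path, overhang: int = 50
) -> None:
    """Write an ``SJ.out.tab`` file from (key, unique_reads, annotated) rows."""
    with open(path, "w") as fh:
        for (chrom, start, end, strand), reads, annotated in rows:
            motif = {"+": 1, "-": 2}.get(strand, 0)
            fh.write(
                f"{chrom}\t{start}\t{end}\t{_SJ_STRAND[strand]}\t{motif}"
                f"\t{int(annotated)}\t{reads}\t0\t{overhang}\n"
            )


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "case_id": str,
                                            "region_id": str})
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Transcript x sample TPM matrix (first column = transcript id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def key_to_str(key: Key) -> str:
    return "{}:{}-{}:{}".format(*key)


def str_to_key(s: str) -> Key:
    chrom, span, strand = s.rsplit(":", 2)
    start, end = span.split("-")
    return (chrom, int(start), int(end), strand)


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path):
    with open(path) as fh:
        return json.load(fh)


def read_sj_dir(directory) -> dict[str, list]:
    """Parse every ``<sample>.SJ.out.tab`` in a directory."""
    from .junction_catalog import parse_junction_table

    out = {}
    for p in sorted(Path(directory).glob("*.SJ.out.tab")):
        sample = p.name[: -len(".SJ.out.tab")]
        out[sample] = parse_junction_table(p, sample)
    return out
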