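"""Readers and writers for the standard formats the pipeline touches.

GFF3 is read and written with the conventional gene -> mRNA/transcript ->
exon hierarchy; coordinates are converted between GFF's 1-based inclusive
convention and the package's internal 0-based half-open intervals here and
nowhere else.  FASTA goes through Biopython, SAM through pysam.
"""
from __future__ import annotations

import math
import urllib.parse
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .model import (
    AlignedRead,
    AnnotationSet,
    AnnotationStructureError,
    ExpressionRecord,
    FormatParseError,
    GeneModel,
    GenomicInterval,
    Hit,
    HitTable,
    SequenceSet,
    TranscriptModel,
)

#: feature types accepted as "transcript" (BRAKER2 emits mRNA, StringTie transcript)
TRANSCRIPT_TYPES = frozenset({"mRNA", "transcript"})


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff(path) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet`.

    Requires gene / mRNA-or-transcript / exon rows linked by Parent
    attributes.  GFF 1-based inclusive coordinates become 0-based
    half-open.  Genes without any exon-bearing transcript are rejected.
    """
    gene_rows: dict[str, str] = {}  # gene id -> scaffold
    gene_order: list[str] = []
    tx_parent: dict[str, str] = {}  # transcript id -> gene id
    tx_order: dict[str, list[str]] = {}  # gene id -> transcript ids in file order
    exons: dict[str, list[GenomicInterval]] = {}  # transcript id -> exons

    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            scaffold, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError:
                raise FormatParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start_1 < 1 or end_1 < start_1:
                raise FormatParseError(
                    f"{path}:{lineno}: invalid coordinate range {start_1}-{end_1}"
                )
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatParseError(f"{path}:{lineno}: gene row lacks ID")
                if gid in gene_rows:
                    raise AnnotationStructureError(f"duplicate gene id {gid}")
                gene_rows[gid] = scaffold
                gene_order.append(gid)
                tx_order.setdefault(gid, [])
            elif ftype in TRANSCRIPT_TYPES:
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise FormatParseError(
                        f"{path}:{lineno}: transcript row lacks ID or Parent"
                    )
                tx_parent[tid] = parent
                tx_order.setdefault(parent, []).append(tid)
                exons.setdefault(tid, [])
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatParseError(f"{path}:{lineno}: exon row lacks Parent")
                for ptid in parent.split(","):
                    exons.setdefault(ptid, []).append(
                        GenomicInterval(scaffold, start_1 - 1, end_1, strand)
                    )
            # other feature types (CDS, UTR, ...) are ignored

    # resolve hierarchy
    for tid, parent in tx_parent.items():
        if parent not in gene_rows:
            raise AnnotationStructureError(
                f"orphan transcript {tid}: Parent {parent!r} is not a gene"
            )
    for tid in exons:
        if tid not in tx_parent:
            raise AnnotationStructureError(
                f"orphan exon parent {tid!r}: no such transcript"
            )

    genes = []
    for gid in gene_order:
        transcripts = []
        for tid in tx_order.get(gid, []):
            ivs = sorted(exons.get(tid, []), key=lambda iv: iv.start)
            if not ivs:
                raise AnnotationStructureError(
                    f"transcript {tid} of gene {gid} has no exons"
                )
            transcripts.append(TranscriptModel(tid, tuple(ivs)))
        if not transcripts:
            raise AnnotationStructureError(f"gene {gid} has no exon-bearing transcript")
        genes.append(GeneModel(gid, tuple(transcripts)))
    return AnnotationSet(genes)


def write_gff(ann: AnnotationSet, path) -> Path:
    """Write an :class:`AnnotationSet` as GFF3 (1-based inclusive coordinates).

    Rows are emitted in deterministic order: scaffold, span start, gene id.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    for scaffold in ann.scaffolds():
        for gene in ann.genes_on(scaffold):
            span = gene.span
            lines.append(
                "\t".join(
                    [
                        scaffold,
                        "glassarch",
                        "gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        span.strand,
                        ".",
                        f"ID={gene.id}",
                    ]
                )
            )
            for tx in gene.transcripts:
                tspan = tx.span
                lines.append(
                    "\t".join(
                        [
                            scaffold,
                            "glassarch",
                            "mRNA",
                            str(tspan.start + 1),
                            str(tspan.end),
                            ".",
                            tx.strand,
                            ".",
                            f"ID={tx.id};Parent={gene.id}",
                        ]
                    )
                )
                for i, ex in enumerate(tx.exons, start=1):
                    lines.append(
                        "\t".join(
                            [
                                scaffold,
                                "glassarch",
                                "exon",
                                str(ex.start + 1),
                                str(ex.end),
                                ".",
                                ex.strand,
                                ".",
                                f"ID={tx.id}.exon{i};Parent={tx.id}",
                            ]
                        )
                    )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fasta(path, alphabet: str = "nucleotide") -> SequenceSet:
    """Read FASTA; ids are the header token up to first whitespace, sequences
    uppercased.  Duplicate ids and empty records are fatal."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatParseError(f"empty FASTA record {rec.id!r} in {path}")
        sequences[rec.id] = seq
    return SequenceSet(sequences, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


_CIGAR_LETTERS = "MIDNSHP=X"


def read_sam(
    path,
    include_secondary: bool = False,
    include_supplementary: bool = False,
) -> list[AlignedRead]:
    """Read a text SAM file into :class:`AlignedRead` records.

    Unmapped reads are always skipped; secondary (0x100) and supplementary
    (0x800) alignments are skipped by default so each read contributes once.
    """
    reads: list[AlignedRead] = []
    try:
        with pysam.AlignmentFile(str(path), "r") as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                if rec.is_secondary and not include_secondary:
                    continue
                if rec.is_supplementary and not include_supplementary:
                    continue
                cigar = tuple(
                    (length, _CIGAR_LETTERS[op]) for op, length in rec.cigartuples or ()
                )
                reads.append(
                    AlignedRead(
                        name=rec.query_name,
                        scaffold=rec.reference_name,
                        pos=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        cigar=cigar,
                        query_seq=rec.query_sequence,
                    )
                )
    except (ValueError, OSError) as exc:
        raise FormatParseError(f"malformed SAM {path}: {exc}") from exc
    return reads


HIT_TABLE_COLUMNS = (
    "query subject pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_hit_table(
    path,
    query_genes: Optional[AnnotationSet] = None,
    subject_genes: Optional[AnnotationSet] = None,
) -> HitTable:
    """Read a 12-column tab-separated hit table (BLAST/DIAMOND outfmt 6).

    Self-hits (query == subject) are dropped.  When gene sets are supplied,
    every id must resolve against them.
    """
    hits: list[Hit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = Hit(
                    query=fields[0],
                    subject=fields[1],
                    percent_identity=float(fields[2]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatParseError(f"{path}:{lineno}: {exc}") from exc
            if hit.query == hit.subject:
                continue
            hits.append(hit)

    offenders: list[str] = []
    if query_genes is not None:
        for h in hits:
            if h.query not in query_genes and h.query not in offenders:
                offenders.append(h.query)
    if subject_genes is not None:
        for h in hits:
            if h.subject not in subject_genes and h.subject not in offenders:
                offenders.append(h.subject)
    if offenders:
        shown = ", ".join(offenders[:10])
        raise AnnotationStructureError(
            f"{len(offenders)} unresolvable hit ids (first 10: {shown})"
        )
    return HitTable(tuple(hits))


def write_hit_table(hits: HitTable, path) -> Path:
    """Write hits in 12-column outfmt-6 layout (placeholder alignment columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query,
                        h.subject,
                        f"{h.percent_identity:.1f}",
                        "100", "0", "0", "1", "100", "1", "100",
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
    return path


def read_expression_table(
    path,
    gene_col: str = "gene",
    log2fc_col: str = "log2FoldChange",
    padj_col: str = "padj",
) -> list[ExpressionRecord]:
    """Read a TSV differential-expression result table.

    Missing/NA adjusted p-values are parsed as absent, never as 0.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, log2fc_col, padj_col):
        if col not in df.columns:
            raise FormatParseError(
                f"{path}: required column {col!r} absent "
                f"(found: {', '.join(df.columns)})"
            )
    records = []
    for _, row in df.iterrows():
        padj = row[padj_col]
        padj = None if pd.isna(padj) else float(padj)
        records.append(
            ExpressionRecord(
                gene=str(row[gene_col]),
                log2fc=float(row[log2fc_col]),
                padj=padj,
            )
        )
    return records


def write_expression_table(
    records: Sequence[ExpressionRecord],
    path,
    gene_col: str = "gene",
    log2fc_col: str = "log2FoldChange",
    padj_col: str = "padj",
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{gene_col}\t{log2fc_col}\t{padj_col}\n")
        for rec in records:
            padj = "NA" if rec.padj is None else f"{rec.padj:.6g}"
            fh.write(f"{rec.gene}\t{rec.log2fc:.6g}\t{padj}\n")
    return path
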