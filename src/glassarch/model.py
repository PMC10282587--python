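"""Shared coordinate and data model used by every pipeline stage.

All internal coordinates are 0-based, half-open ``[start, end)`` intervals.
Format readers and writers (see :mod:`glassarch.core_io`) convert to and
from 1-based inclusive conventions at the boundary, so interval arithmetic
inside the package never needs off-by-one corrections.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

VALID_STRANDS = frozenset({"+", "-", "."})

#: query-consuming CIGAR operations (SAM spec)
QUERY_CONSUMING = frozenset({"M", "I", "S", "=", "X"})
#: CIGAR operations accepted by the model
CIGAR_OPS = frozenset({"M", "I", "D", "N", "S", "H", "P", "=", "X"})


class GlassArchError(Exception):
    """Base class for all package errors."""


class FormatParseError(GlassArchError):
    """A file could not be parsed (malformed line, wrong column count...)."""


class AnnotationStructureError(GlassArchError):
    """Feature hierarchy is inconsistent (orphans, duplicates, no exons)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a scaffold.

    ``length == end - start`` and is always >= 1.
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.scaffold}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.scaffold}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same scaffold)."""
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered, disjoint exons on a single scaffold.

    Introns are the gaps between consecutive exons and are guaranteed to
    have length >= 1 by the disjointness requirement.
    """

    id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationStructureError(f"transcript {self.id} has no exons")
        scaf = self.exons[0].scaffold
        strand = self.exons[0].strand
        prev_end = -1
        for ex in self.exons:
            if ex.scaffold != scaf:
                raise AnnotationStructureError(
                    f"transcript {self.id} spans scaffolds {scaf} and {ex.scaffold}"
                )
            if ex.strand != strand:
                raise AnnotationStructureError(
                    f"transcript {self.id} mixes strands"
                )
            if ex.start <= prev_end:
                raise AnnotationStructureError(
                    f"transcript {self.id}: exons unsorted or overlapping/abutting "
                    f"at {ex.start}"
                )
            prev_end = ex.end

    @property
    def scaffold(self) -> str:
        return self.exons[0].scaffold

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.scaffold, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts on a single scaffold.

    The gene span is the union envelope over all transcripts, so a gene
    is "contained in an intron" only if every isoform is.
    """

    id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationStructureError(f"gene {self.id} has no transcripts")
        scaf = self.transcripts[0].scaffold
        for tx in self.transcripts:
            if tx.scaffold != scaf:
                raise AnnotationStructureError(
                    f"gene {self.id} has transcripts on multiple scaffolds"
                )

    @property
    def scaffold(self) -> str:
        return self.transcripts[0].scaffold

    @property
    def span(self) -> GenomicInterval:
        start = min(tx.span.start for tx in self.transcripts)
        end = max(tx.span.end for tx in self.transcripts)
        strands = {tx.strand for tx in self.transcripts}
        strand = strands.pop() if len(strands) == 1 else "."
        return GenomicInterval(self.scaffold, start, end, strand)

    @property
    def exonic_union_length(self) -> int:
        """Length of the union of all exon intervals over all transcripts."""
        ivs = sorted(
            (ex.start, ex.end) for tx in self.transcripts for ex in tx.exons
        )
        total = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        return total


class AnnotationSet:
    """Gene models indexed by id and by scaffold (ordered by span start)."""

    def __init__(self, genes) -> None:
        self._genes: dict[str, GeneModel] = {}
        by_scaffold: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.id in self._genes:
                raise AnnotationStructureError(f"duplicate gene id {g.id}")
            self._genes[g.id] = g
            by_scaffold.setdefault(g.scaffold, []).append(g)
        self._by_scaffold = {
            scaf: tuple(sorted(gs, key=lambda g: (g.span.start, g.id)))
            for scaf, gs in by_scaffold.items()
        }

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._genes == other._genes

    def scaffolds(self) -> list[str]:
        return sorted(self._by_scaffold)

    def genes_on(self, scaffold: str) -> tuple[GeneModel, ...]:
        """Genes on *scaffold*, sorted by span start then id."""
        if scaffold not in self._by_scaffold:
            raise KeyError(f"scaffold {scaffold!r} not in annotation")
        return self._by_scaffold[scaffold]

    def transcript_count(self) -> int:
        return sum(len(g.transcripts) for g in self)


@dataclass
class SequenceSet(Mapping):
    """Identifier -> residue string, with an alphabet tag."""

    sequences: dict[str, str]
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class AlignedRead:
    """Minimal view of one mapped SAM record."""

    name: str
    scaffold: str
    pos: int  # leftmost mapped base, 0-based
    strand: str  # "+" or "-"
    cigar: tuple[tuple[int, str], ...]  # (length, op)
    query_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.name}: strand must be + or -")
        for length, op in self.cigar:
            if op not in CIGAR_OPS:
                raise FormatParseError(f"read {self.name}: unknown CIGAR op {op!r}")
            if length < 1:
                raise FormatParseError(f"read {self.name}: CIGAR length {length} < 1")
        if self.query_seq is not None:
            consumed = sum(
                ln for ln, op in self.cigar if op in QUERY_CONSUMING
            )
            if consumed != len(self.query_seq):
                raise FormatParseError(
                    f"read {self.name}: CIGAR consumes {consumed} bases but query "
                    f"is {len(self.query_seq)}"
                )


@dataclass(frozen=True)
class Hit:
    """One pairwise similarity record (BLAST/DIAMOND outfmt-6 style)."""

    query: str
    subject: str
    percent_identity: float
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query}->{self.subject}")
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.query}->{self.subject}")


@dataclass(frozen=True)
class HitTable:
    """Immutable collection of hits, optionally bound to gene sets."""

    hits: tuple[Hit, ...]

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self.hits)

    def queries(self) -> set[str]:
        return {h.query for h in self.hits}

    def subjects(self) -> set[str]:
        return {h.subject for h in self.hits}


@dataclass(frozen=True)
class ExpressionRecord:
    """One row of a differential-expression result table (consumed as input)."""

    gene: str
    log2fc: float
    padj: Optional[float] = None
    mean_count_body: Optional[float] = None
    mean_count_tip: Optional[float] = None

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj {self.padj} outside [0,1] for {self.gene}")
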