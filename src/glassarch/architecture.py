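"""Genome-architecture statistics for compact animal genomes.

Covers nested-gene detection (genes whose whole span lies inside an intron
of another gene, a hallmark of compact genomes such as those of glass
sponges), bulk annotation statistics, per-scaffold intron profiles,
assembly contiguity (N50 and the N50/total ratio used to judge closeness
to chromosome scale), and a GC/RNA-coverage screen for bacterial
contaminant scaffolds.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional

import numpy as np

from .model import AnnotationSet, GenomicInterval, SequenceSet


class NestedPair(NamedTuple):
    nested_gene: str
    host_gene: str
    host_transcript: str
    host_intron: GenomicInterval


@dataclass(frozen=True)
class NestedGeneReport:
    nested_pairs: tuple[NestedPair, ...]
    nested_gene_count: int
    nested_fraction: float
    nested_exonic_fraction: float
    total_genes: int

    @property
    def nested_gene_ids(self) -> frozenset[str]:
        return frozenset(p.nested_gene for p in self.nested_pairs)


@dataclass(frozen=True)
class GenomeStats:
    gene_count: int
    transcript_count: int
    single_exon_transcript_count: int
    mean_gene_length: Optional[float]
    mean_transcript_length: Optional[float]
    total_exonic_bp: int
    intron_count: int
    mean_intron_length: Optional[float]


@dataclass(frozen=True)
class IntronProfile:
    scaffold: str
    unique_introns: tuple[tuple[int, int], ...]
    count: int
    mean_length: Optional[float]
    total_length: int
    lengths_sorted_desc: tuple[int, ...]


@dataclass(frozen=True)
class ContiguityStats:
    total_length: int
    scaffold_count: int
    n50: int
    n50_over_total: float
    threshold: int
    scaffolds_over_threshold: int
    fraction_over_threshold: float


@dataclass(frozen=True)
class ScaffoldScreenRecord:
    scaffold: str
    gc_fraction: float
    mean_rna_coverage: float
    length: int
    flagged_bacterial: bool


def detect_nested_genes(ann: AnnotationSet) -> NestedGeneReport:
    """Find genes wholly contained in an intron of another gene.

    Gene G is nested in host H iff both are on the same scaffold, G != H,
    and G's span (union envelope over isoforms) lies entirely within a
    single intron of at least one transcript of H.  Strand is ignored.
    Each nested gene is counted once even with multiple hosts; all
    (gene, host, transcript, intron) relations are listed exhaustively.
    """
    pairs: list[NestedPair] = []
    nested_ids: set[str] = set()
    for scaffold in ann.scaffolds():
        genes = ann.genes_on(scaffold)
        intron_meta: list[tuple[str, str]] = []
        starts: list[int] = []
        ends: list[int] = []
        for g in genes:
            for tx in g.transcripts:
                for intr in tx.introns:
                    intron_meta.append((g.id, tx.id))
                    starts.append(intr.start)
                    ends.append(intr.end)
        if not intron_meta:
            continue
        starts_a = np.asarray(starts)
        ends_a = np.asarray(ends)
        for g in genes:
            span = g.span
            mask = (starts_a <= span.start) & (ends_a >= span.end)
            for idx in np.nonzero(mask)[0]:
                host_id, tx_id = intron_meta[idx]
                if host_id == g.id:
                    continue
                pairs.append(
                    NestedPair(
                        g.id,
                        host_id,
                        tx_id,
                        GenomicInterval(scaffold, starts[idx], ends[idx]),
                    )
                )
                nested_ids.add(g.id)

    total = len(ann)
    total_exonic = sum(g.exonic_union_length for g in ann)
    nested_exonic = sum(ann[gid].exonic_union_length for gid in nested_ids)
    return NestedGeneReport(
        nested_pairs=tuple(pairs),
        nested_gene_count=len(nested_ids),
        nested_fraction=(len(nested_ids) / total) if total else 0.0,
        nested_exonic_fraction=(nested_exonic / total_exonic) if total_exonic else 0.0,
        total_genes=total,
    )


def genome_bulk_stats(ann: AnnotationSet) -> GenomeStats:
    """Bulk annotation statistics: counts and mean lengths.

    Mean gene length uses the gene span; mean transcript length uses the
    summed exon length.  Exonic bp per gene is the union of its exon
    intervals over all isoforms.  Introns are counted per transcript
    (not deduplicated).
    """
    gene_count = len(ann)
    gene_lengths = []
    tx_lengths = []
    intron_lengths = []
    single_exon = 0
    total_exonic = 0
    for g in ann:
        gene_lengths.append(g.span.length)
        total_exonic += g.exonic_union_length
        for tx in g.transcripts:
            tx_lengths.append(tx.exonic_length)
            if len(tx.exons) == 1:
                single_exon += 1
            for intr in tx.introns:
                intron_lengths.append(intr.length)

    def _mean(values) -> Optional[float]:
        return float(np.mean(values)) if values else None

    return GenomeStats(
        gene_count=gene_count,
        transcript_count=len(tx_lengths),
        single_exon_transcript_count=single_exon,
        mean_gene_length=_mean(gene_lengths),
        mean_transcript_length=_mean(tx_lengths),
        total_exonic_bp=total_exonic,
        intron_count=len(intron_lengths),
        mean_intron_length=_mean(intron_lengths),
    )


def scaffold_intron_profile(ann: AnnotationSet, scaffold: str) -> IntronProfile:
    """Unique introns of one scaffold: deduplicated by exact (start, end)."""
    genes = ann.genes_on(scaffold)  # raises KeyError naming the scaffold
    unique: set[tuple[int, int]] = set()
    for g in genes:
        for tx in g.transcripts:
            for intr in tx.introns:
                unique.add((intr.start, intr.end))
    ordered = tuple(sorted(unique))
    lengths = sorted((e - s for s, e in ordered), reverse=True)
    total = sum(lengths)
    return IntronProfile(
        scaffold=scaffold,
        unique_introns=ordered,
        count=len(ordered),
        mean_length=(total / len(ordered)) if ordered else None,
        total_length=total,
        lengths_sorted_desc=tuple(lengths),
    )


def assembly_contiguity(seqs: SequenceSet, threshold: int = 500_000) -> ContiguityStats:
    """Assembly contiguity statistics.

    N50 is the length of the sequence at which the descending cumulative
    sum first reaches >= half the total (ties resolved toward the larger
    scaffold by the descending scan).  ``fraction_over_threshold`` is the
    fraction of total assembly length held in scaffolds strictly longer
    than *threshold*.
    """
    if not seqs:
        raise ValueError("assembly_contiguity requires at least one sequence")
    lengths = sorted((len(seqs[name]) for name in seqs), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if cum >= half:
            n50 = length
            break
    over = [length for length in lengths if length > threshold]
    return ContiguityStats(
        total_length=total,
        scaffold_count=len(lengths),
        n50=n50,
        n50_over_total=n50 / total,
        threshold=threshold,
        scaffolds_over_threshold=len(over),
        fraction_over_threshold=sum(over) / total,
    )


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous A/C/G/T bases only (N never dilutes GC)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def screen_contaminant_scaffolds(
    seqs: SequenceSet,
    coverage: Mapping[str, float],
    gc_threshold: float = 0.40,
    cov_threshold: float = 1.0,
) -> list[ScaffoldScreenRecord]:
    """Flag candidate bacterial scaffolds by GC content and RNA coverage.

    A scaffold is flagged when its GC fraction exceeds *gc_threshold* AND
    its mean RNA coverage is below *cov_threshold* (bacterial mRNAs lack
    poly-A tails, so such scaffolds recruit essentially no RNA reads).
    The full per-scaffold table is returned for blob-style plotting.
    """
    records = []
    for name in sorted(seqs):
        seq = seqs[name]
        gc = gc_fraction(seq)
        cov = float(coverage.get(name, 0.0))
        records.append(
            ScaffoldScreenRecord(
                scaffold=name,
                gc_fraction=gc,
                mean_rna_coverage=cov,
                length=len(seq),
                flagged_bacterial=(gc > gc_threshold) and (cov < cov_threshold),
            )
        )
    return records
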