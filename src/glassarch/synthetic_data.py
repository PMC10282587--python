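"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — compact annotated genomes with genes planted inside host introns,
ortholog pairs related by inversions/insertions/tandem expansions,
long reads carrying a fixed 5' spliced leader on a tunable fraction of
molecules, proteomes with planted residue-biased proteins, and assembly
metric tables with a known dominating assembly — and records the planted
facts in a :class:`TruthBundle` so detectors can be scored exactly.
All generators are deterministic per seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biomin_screen import STANDARD_AA, reference_percentiles
from .model import (
    AnnotationSet,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    Hit,
    HitTable,
    SequenceSet,
    TranscriptModel,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default simulated spliced leader (37 bp, fixed so truths are stable per seed)
DEFAULT_LEADER = "ATTCTATTTCGGTGTACTGGTTCCCTGACCAATTTTG"

#: SwissProt-like background amino-acid frequencies, order = STANDARD_AA
BACKGROUND_AA_FREQ = np.array(
    [
        0.0825, 0.0138, 0.0545, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0665,
        0.0536, 0.0686, 0.0110, 0.0292,
    ]
)


@dataclass
class TruthBundle:
    """Planted facts of one simulation; only fields the generator sets are filled."""

    nested_gene_ids: tuple[str, ...] = ()
    host_map: dict[str, str] = field(default_factory=dict)
    single_exon_transcript_count: Optional[int] = None
    coverage: dict[str, float] = field(default_factory=dict)
    contaminant_scaffolds: tuple[str, ...] = ()
    anchor_pairs: tuple[tuple[str, str], ...] = ()
    expected_blocks: tuple[tuple[str, str, tuple[tuple[str, str], ...], str], ...] = ()
    inserted_genes: tuple[str, ...] = ()
    tandem_members: tuple[str, ...] = ()
    family_map: dict[str, str] = field(default_factory=dict)
    leader: Optional[str] = None
    leader_flags: dict[str, bool] = field(default_factory=dict)
    total_mapped: Optional[int] = None
    planted_bias: dict[str, str] = field(default_factory=dict)
    best_assembly: Optional[str] = None


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply iid substitution errors at the given per-base rate."""
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < rate
    for i in np.nonzero(mask)[0]:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# annotated genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimSpec:
    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length: int = 400_000
    gene_count: int = 400
    single_exon_fraction: float = 0.3
    nested_fraction: float = 0.0
    gc: float = 0.36
    n_contaminant: int = 0
    contaminant_gc: float = 0.55
    contaminant_length: int = 40_000
    exon_log_mu: float = math.log(160.0)
    exon_log_sigma: float = 0.5
    intron_log_mu: float = math.log(300.0)
    intron_log_sigma: float = 0.6
    intergenic_log_mu: float = math.log(500.0)
    intergenic_log_sigma: float = 0.5
    max_exons: int = 6
    nested_margin: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.nested_fraction <= 0.5):
            raise ValueError("nested_fraction must be in [0, 0.5]")
        for name in ("n_scaffolds", "gene_count", "n_contaminant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_annotated_genome(
    spec: GenomeSimSpec,
) -> tuple[SequenceSet, AnnotationSet, TruthBundle]:
    """Simulate a compact annotated genome with planted nested genes.

    Top-level genes are packed left-to-right without overlap; each planted
    nested gene is a single-exon gene strictly interior to one intron of a
    multi-exon host (margins >= ``nested_margin``), so recovery by the
    detector is unambiguous.  Contaminant scaffolds carry no genes, higher
    GC, and zero RNA coverage.
    """
    rng = np.random.default_rng(spec.seed)
    n_nested = round(spec.nested_fraction * spec.gene_count)
    n_top = spec.gene_count - n_nested

    single_flags = rng.random(n_top) < spec.single_exon_fraction
    multi_positions = [i for i in range(n_top) if not single_flags[i]]
    if len(multi_positions) < n_nested:
        raise ValueError(
            f"cannot plant {n_nested} nested genes: only {len(multi_positions)} "
            "multi-exon hosts available; lower single_exon_fraction"
        )
    host_positions = set(
        int(i)
        for i in rng.choice(multi_positions, size=n_nested, replace=False)
    )

    def draw_len(mu: float, sigma: float, floor: int) -> int:
        return max(int(round(rng.lognormal(mu, sigma))), floor)

    genes: list[GeneModel] = []
    nested_ids: list[str] = []
    host_map: dict[str, str] = {}
    gid = 0
    scaf_i = 0
    cursor = 0
    scaffold_names = [f"scaffold_{i + 1:03d}" for i in range(spec.n_scaffolds)]

    for i in range(n_top):
        gap = draw_len(spec.intergenic_log_mu, spec.intergenic_log_sigma, 50)
        is_host = i in host_positions
        nested_len = (
            draw_len(spec.exon_log_mu, spec.exon_log_sigma, 40) if is_host else 0
        )
        if single_flags[i]:
            exon_lens = [draw_len(spec.exon_log_mu, spec.exon_log_sigma, 60)]
            intron_lens: list[int] = []
            host_intron = -1
        else:
            k = int(rng.integers(2, spec.max_exons + 1))
            exon_lens = [
                draw_len(spec.exon_log_mu, spec.exon_log_sigma, 40) for _ in range(k)
            ]
            intron_lens = [
                draw_len(spec.intron_log_mu, spec.intron_log_sigma, 50)
                for _ in range(k - 1)
            ]
            host_intron = int(rng.integers(k - 1)) if is_host else -1
            if is_host:
                pad = int(rng.integers(0, 60))
                intron_lens[host_intron] = (
                    nested_len + 2 * spec.nested_margin + pad + 2
                )
        total_len = sum(exon_lens) + sum(intron_lens)

        start = cursor + gap
        if start + total_len > spec.scaffold_length - 100:
            scaf_i += 1
            if scaf_i >= spec.n_scaffolds:
                raise ValueError(
                    "infeasible packing: gene set does not fit the configured "
                    "scaffold space"
                )
            cursor = 0
            start = gap
        scaffold = scaffold_names[scaf_i]

        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        intron_spans: list[tuple[int, int]] = []
        for j, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(scaffold, pos, pos + elen, strand))
            pos += elen
            if j < len(intron_lens):
                intron_spans.append((pos, pos + intron_lens[j]))
                pos += intron_lens[j]
        gid += 1
        gene_id = f"g{gid:05d}"
        genes.append(
            GeneModel(gene_id, (TranscriptModel(f"{gene_id}.t1", tuple(exons)),))
        )
        cursor = start + total_len

        if is_host:
            istart, iend = intron_spans[host_intron]
            slack = (iend - istart) - nested_len - 2 * spec.nested_margin
            offset = int(rng.integers(0, slack + 1))
            nstart = istart + spec.nested_margin + offset
            nstrand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            nid = f"g{gid:05d}"
            genes.append(
                GeneModel(
                    nid,
                    (
                        TranscriptModel(
                            f"{nid}.t1",
                            (GenomicInterval(scaffold, nstart, nstart + nested_len, nstrand),),
                        ),
                    ),
                )
            )
            nested_ids.append(nid)
            host_map[nid] = gene_id

    sequences: dict[str, str] = {}
    coverage: dict[str, float] = {}
    for name in scaffold_names:
        sequences[name] = random_sequence(rng, spec.scaffold_length, spec.gc)
        coverage[name] = float(rng.uniform(20.0, 80.0))
    contaminants = []
    for c in range(spec.n_contaminant):
        name = f"contig_bact_{c + 1:02d}"
        sequences[name] = random_sequence(
            rng, spec.contaminant_length, spec.contaminant_gc
        )
        coverage[name] = 0.0
        contaminants.append(name)

    ann = AnnotationSet(genes)
    single_exon_total = sum(
        1 for g in ann for tx in g.transcripts if len(tx.exons) == 1
    )
    truth = TruthBundle(
        nested_gene_ids=tuple(nested_ids),
        host_map=host_map,
        single_exon_transcript_count=single_exon_total,
        coverage=coverage,
        contaminant_scaffolds=tuple(contaminants),
    )
    return SequenceSet(sequences), ann, truth


# ---------------------------------------------------------------------------
# ortholog pair
# ---------------------------------------------------------------------------

@dataclass
class OrthoPairSimSpec:
    seed: int = 0
    n_genes: int = 120
    n_scaffolds_a: int = 2
    n_scaffolds_b: int = 3
    inversions: tuple[tuple[int, int], ...] = ()  # (start global index, length)
    insertion_rate: float = 0.0
    tandem_size: int = 0
    tandem_interleave: int = 1
    paralog_hit_rate: float = 0.0
    spurious_hit_rate: float = 0.0
    gene_length: int = 600
    gene_spacing: int = 1500

    def __post_init__(self) -> None:
        spans = sorted((s, s + l) for s, l in self.inversions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("inversion segments must be disjoint")
        for s, l in self.inversions:
            if s < 0 or l < 1 or s + l > self.n_genes:
                raise ValueError(f"inversion ({s},{l}) outside gene range")


def _partition(n: int, k: int) -> list[tuple[int, int]]:
    """Split range(n) into k near-equal contiguous chunks."""
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    return [(int(a), int(b)) for a, b in zip(bounds, bounds[1:])]


def _linear_annotation(
    scaffold_orders: dict[str, list[str]], gene_length: int, spacing: int
) -> AnnotationSet:
    genes = []
    for scaffold, ids in scaffold_orders.items():
        for j, gid in enumerate(ids):
            start = 100 + j * spacing
            genes.append(
                GeneModel(
                    gid,
                    (
                        TranscriptModel(
                            f"{gid}.t1",
                            (GenomicInterval(scaffold, start, start + gene_length, "+"),),
                        ),
                    ),
                )
            )
    return AnnotationSet(genes)


def simulate_ortholog_pair(
    spec: OrthoPairSimSpec,
) -> tuple[AnnotationSet, AnnotationSet, HitTable, TruthBundle]:
    """Simulate two annotations related by inversions / insertions / tandems.

    Genome B's gene order is genome A's order partitioned onto B scaffolds,
    with the configured segments inverted, lineage-specific single-exon
    genes inserted at ``insertion_rate``, and (in genome A) an optional
    interleaved tandem family.  The hit table holds the true ortholog hits
    at top bitscore plus configured paralog/spurious noise at strictly
    lower bitscore, so best-hit reduction recovers the planted map.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    a_ids = [f"avG{i:04d}" for i in range(n)]
    b_ids = [f"omG{i:04d}" for i in range(n)]

    a_chunks = _partition(n, spec.n_scaffolds_a)
    b_chunks = _partition(n, spec.n_scaffolds_b)
    a_scaffold_of = {}
    for ci, (s, e) in enumerate(a_chunks):
        for i in range(s, e):
            a_scaffold_of[i] = f"scafA{ci + 1:02d}"
    for s, l in spec.inversions:
        if not any(cs <= s and s + l <= ce for cs, ce in b_chunks):
            raise ValueError(
                f"inversion ({s},{l}) crosses a genome-B scaffold boundary"
            )

    # genome B order: global ortholog indices per scaffold, inversions applied
    b_orders_idx: dict[str, list[int]] = {}
    for ci, (s, e) in enumerate(b_chunks):
        idx = list(range(s, e))
        for inv_s, inv_l in spec.inversions:
            if s <= inv_s and inv_s + inv_l <= e:
                lo, hi = inv_s - s, inv_s - s + inv_l
                idx[lo:hi] = idx[lo:hi][::-1]
        b_orders_idx[f"scafB{ci + 1:02d}"] = idx

    # lineage-specific insertions in B (None marks an inserted gene)
    inserted: list[str] = []
    b_orders: dict[str, list[str]] = {}
    for scaffold, idx in b_orders_idx.items():
        out: list[str] = []
        for i in idx:
            if rng.random() < spec.insertion_rate:
                nid = f"omX{len(inserted):04d}"
                inserted.append(nid)
                out.append(nid)
            out.append(b_ids[i])
        b_orders[scaffold] = out

    # tandem family planted in genome A, interleaved with ordinary genes
    a_orders: dict[str, list[str]] = {}
    for ci, (s, e) in enumerate(a_chunks):
        a_orders[f"scafA{ci + 1:02d}"] = [a_ids[i] for i in range(s, e)]
    tandem_members: list[str] = []
    family_map: dict[str, str] = {}
    if spec.tandem_size > 0:
        scaffold = sorted(a_orders)[0]
        order = a_orders[scaffold]
        pos = len(order) // 3
        head, rest = order[:pos], order[pos:]
        merged = list(head)
        ri = 0
        for m in range(spec.tandem_size):
            mid = f"avT{m:03d}"
            tandem_members.append(mid)
            family_map[mid] = "fam_tandem"
            merged.append(mid)
            if m < spec.tandem_size - 1:
                for _ in range(spec.tandem_interleave):
                    if ri < len(rest):
                        merged.append(rest[ri])
                        ri += 1
        merged.extend(rest[ri:])
        a_orders[scaffold] = merged

    ann_a = _linear_annotation(a_orders, spec.gene_length, spec.gene_spacing)
    ann_b = _linear_annotation(b_orders, spec.gene_length, spec.gene_spacing)

    hits: list[Hit] = []
    for i in range(n):
        hits.append(
            Hit(
                query=a_ids[i],
                subject=b_ids[i],
                percent_identity=float(rng.uniform(60, 95)),
                bitscore=float(rng.uniform(300, 600)),
                evalue=float(10.0 ** -rng.uniform(30, 80)),
            )
        )
    n_paralog = round(spec.paralog_hit_rate * n)
    n_spurious = round(spec.spurious_hit_rate * n)
    for _ in range(n_paralog + n_spurious):
        qi = int(rng.integers(n))
        si = int(rng.integers(n))
        if si == qi:
            si = (si + 1) % n
        hits.append(
            Hit(
                query=a_ids[qi],
                subject=b_ids[si],
                percent_identity=float(rng.uniform(30, 60)),
                bitscore=float(rng.uniform(60, 250)),
                evalue=float(10.0 ** -rng.uniform(3, 20)),
            )
        )

    truth = TruthBundle(
        anchor_pairs=tuple((a_ids[i], b_ids[i]) for i in range(n)),
        expected_blocks=_expected_blocks(b_orders_idx, a_scaffold_of, a_ids, b_ids),
        inserted_genes=tuple(inserted),
        tandem_members=tuple(tandem_members),
        family_map=family_map,
    )
    return ann_a, ann_b, HitTable(tuple(hits)), truth


def _expected_blocks(
    b_orders_idx: dict[str, list[int]],
    a_scaffold_of: dict[int, str],
    a_ids: list[str],
    b_ids: list[str],
) -> tuple[tuple[str, str, tuple[tuple[str, str], ...], str], ...]:
    """Maximal collinear runs implied by the construction, as
    (scaffold_a, scaffold_b, anchors sorted by genome-A order, orientation)."""
    blocks = []
    for scaffold_b in sorted(b_orders_idx):
        idx = b_orders_idx[scaffold_b]
        run: list[int] = []
        direction = 0

        def close() -> None:
            nonlocal run, direction
            if run:
                ordered = run if run[0] < run[-1] else run[::-1]
                orientation = "+" if (len(run) == 1 or run[1] > run[0]) else "-"
                blocks.append(
                    (
                        a_scaffold_of[run[0]],
                        scaffold_b,
                        tuple((a_ids[i], b_ids[i]) for i in ordered),
                        orientation,
                    )
                )
            run, direction = [], 0

        for i in idx:
            if not run:
                run.append(i)
                continue
            step = i - run[-1]
            same_scaf = a_scaffold_of[i] == a_scaffold_of[run[0]]
            if same_scaf and abs(step) == 1 and (direction in (0, step)):
                run.append(i)
                direction = step
            else:
                close()
                run.append(i)
        close()
    return tuple(blocks)


# ---------------------------------------------------------------------------
# spliced-leader reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    seed: int = 0
    n_reads: int = 1000
    leader: str = DEFAULT_LEADER
    leader_fraction: float = 0.04
    error_rate: float = 0.0
    n_transcripts: int = 25
    genome_length: int = 60_000
    minus_fraction: float = 0.5
    scaffold_name: str = "sim_scaffold"
    transcript_len_range: tuple[int, int] = (400, 1200)

    def __post_init__(self) -> None:
        if not (0.0 <= self.leader_fraction <= 1.0):
            raise ValueError("leader_fraction must be in [0,1]")


def simulate_leader_reads(spec: ReadSimSpec, path) -> tuple[Path, TruthBundle]:
    """Write a SAM file of full-length cDNA alignments with soft-clipped leaders.

    Leader-bearing reads get the leader prepended to the transcript and
    soft-clipped in the emitted record; minus-strand transcripts are
    emitted with reference-forward SEQ (genomic segment followed by the
    reverse-complemented leader) and a trailing S op, as an aligner would.
    Substitution errors are applied to both leader and aligned bases.
    """
    rng = np.random.default_rng(spec.seed)
    genome = random_sequence(rng, spec.genome_length, gc=0.4)
    lo, hi = spec.transcript_len_range
    transcripts = []
    for _ in range(spec.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, spec.genome_length - length))
        strand = "-" if rng.random() < spec.minus_fraction else "+"
        transcripts.append((start, length, strand))

    path = Path(path)
    leader_flags: dict[str, bool] = {}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{spec.scaffold_name}\tLN:{spec.genome_length}\n")
        for i in range(spec.n_reads):
            t = int(rng.integers(spec.n_transcripts))
            start, length, strand = transcripts[t]
            name = f"read_{i + 1:06d}"
            has_leader = bool(rng.random() < spec.leader_fraction)
            leader_flags[name] = has_leader
            aligned = _mutate(genome[start : start + length], spec.error_rate, rng)
            leader = (
                _mutate(spec.leader, spec.error_rate, rng) if has_leader else ""
            )
            llen = len(leader)
            if strand == "+":
                seq = leader + aligned
                cigar = (f"{llen}S" if llen else "") + f"{length}M"
                flag = 0
            else:
                seq = aligned + reverse_complement(leader)
                cigar = f"{length}M" + (f"{llen}S" if llen else "")
                flag = 16
            fh.write(
                "\t".join(
                    [
                        name,
                        str(flag),
                        spec.scaffold_name,
                        str(start + 1),
                        "60",
                        cigar,
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                    ]
                )
                + "\n"
            )
    truth = TruthBundle(
        leader=spec.leader,
        leader_flags=leader_flags,
        total_mapped=spec.n_reads,
    )
    return path, truth


# ---------------------------------------------------------------------------
# proteome with planted compositional bias
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSimSpec:
    seed: int = 0
    n_reference: int = 2000
    n_proteome: int = 1000
    planted_fraction: float = 0.02
    bias_residues: tuple[str, ...] = ("D", "E", "H", "P", "S", "T")
    bias_margin: float = 0.05
    length_log_mu: float = math.log(250.0)
    length_log_sigma: float = 0.4
    min_len: int = 50
    dirichlet_conc: float = 200.0
    q: float = 99.0
    planted_log2fc_mu: float = 5.0
    planted_log2fc_sigma: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_fraction <= 0.2):
            raise ValueError("planted_fraction must be in [0, 0.2]")


def _draw_protein(rng: np.random.Generator, spec: ProteomeSimSpec) -> str:
    comp = rng.dirichlet(BACKGROUND_AA_FREQ * spec.dirichlet_conc)
    length = max(int(round(rng.lognormal(spec.length_log_mu, spec.length_log_sigma))),
                 spec.min_len + 10)
    idx = rng.choice(20, size=length, p=comp)
    return "".join(STANDARD_AA[i] for i in idx)


def simulate_proteome(
    spec: ProteomeSimSpec,
) -> tuple[SequenceSet, SequenceSet, list[ExpressionRecord], TruthBundle]:
    """Simulate a proteome + reference with planted residue-biased proteins.

    The reference is drawn from the background composition only; planted
    proteins exceed the reference's q-th percentile frequency for their
    biased residue by construction (margin ``bias_margin``).  The paired
    expression table gives planted proteins strong upregulation and
    near-zero adjusted p-values; background p-values are uniform.
    """
    rng = np.random.default_rng(spec.seed)
    reference = SequenceSet(
        {f"ref{i + 1:05d}": _draw_protein(rng, spec) for i in range(spec.n_reference)},
        alphabet="protein",
    )
    table = reference_percentiles(reference, q=spec.q, min_len=spec.min_len)

    n_planted = round(spec.planted_fraction * spec.n_proteome)
    planted_idx = set(
        int(i) for i in rng.choice(spec.n_proteome, size=n_planted, replace=False)
    )
    proteome: dict[str, str] = {}
    planted_bias: dict[str, str] = {}
    records: list[ExpressionRecord] = []
    for i in range(spec.n_proteome):
        pid = f"prot{i + 1:05d}"
        if i in planted_idx:
            residue = spec.bias_residues[int(rng.integers(len(spec.bias_residues)))]
            target = min(table.values[residue] + spec.bias_margin, 0.8)
            body = _draw_protein(rng, spec)
            n_biased = math.ceil(target * len(body))
            chars = list(body)
            positions = rng.choice(len(chars), size=n_biased, replace=False)
            for p in positions:
                chars[p] = residue
            proteome[pid] = "".join(chars)
            planted_bias[pid] = residue
            records.append(
                ExpressionRecord(
                    gene=pid,
                    log2fc=max(
                        float(rng.normal(spec.planted_log2fc_mu, spec.planted_log2fc_sigma)),
                        1.0,
                    ),
                    padj=float(10.0 ** rng.uniform(-10, -5)),
                )
            )
        else:
            proteome[pid] = _draw_protein(rng, spec)
            records.append(
                ExpressionRecord(
                    gene=pid,
                    log2fc=float(rng.normal(0.0, 1.0)),
                    padj=float(rng.uniform(0.0, 1.0)),
                )
            )
    truth = TruthBundle(planted_bias=planted_bias)
    return SequenceSet(proteome, alphabet="protein"), reference, records, truth


# ---------------------------------------------------------------------------
# assembly metric tables
# ---------------------------------------------------------------------------

_METRIC_DIRECTIONS = {
    "n50": +1,
    "size_delta_pct": -1,
    "mean_scaffold_len": +1,
    "scaffold_count": -1,
    "busco_single_complete": +1,
    "rna_map_pct": +1,
    "dna_map_pct": +1,
}


def simulate_assembly_metrics(
    seed: int = 0, n_assemblies: int = 5, dominating: bool = True
) -> tuple[pd.DataFrame, TruthBundle]:
    """Random assembly-metric table; optionally one assembly dominates all
    metrics (given their optimisation directions)."""
    if n_assemblies < 1:
        raise ValueError("n_assemblies must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"asm{i + 1:02d}" for i in range(n_assemblies)]
    table = pd.DataFrame(
        {
            "n50": rng.uniform(5e5, 5e6, n_assemblies),
            "size_delta_pct": rng.uniform(1.0, 30.0, n_assemblies),
            "mean_scaffold_len": rng.uniform(2e4, 8e5, n_assemblies),
            "scaffold_count": rng.integers(100, 4000, n_assemblies).astype(float),
            "busco_single_complete": rng.uniform(70.0, 99.0, n_assemblies),
            "rna_map_pct": rng.uniform(60.0, 99.0, n_assemblies),
            "dna_map_pct": rng.uniform(60.0, 99.0, n_assemblies),
        },
        index=ids,
    )
    best: Optional[str] = None
    if dominating:
        best = ids[int(rng.integers(n_assemblies))]
        for metric, sign in _METRIC_DIRECTIONS.items():
            col = table[metric]
            if sign > 0:
                table.loc[best, metric] = col.max() * 1.05 + 1.0
            else:
                table.loc[best, metric] = max(col.min() * 0.95 - 1.0, 0.0)
    return table, TruthBundle(best_assembly=best)
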