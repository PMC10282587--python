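"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (all-pairs scans, closed-form
enumeration) and never share code with the implementation paths they
check.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

from glassarch.model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


def make_gene(gene_id, scaffold, exon_coords, strand="+", tx_suffix=".t1"):
    """Build a single-transcript gene from a list of (start, end) pairs."""
    exons = tuple(
        GenomicInterval(scaffold, s, e, strand) for s, e in exon_coords
    )
    return GeneModel(gene_id, (TranscriptModel(f"{gene_id}{tx_suffix}", exons),))


def random_messy_annotation(
    rng: np.random.Generator,
    n_genes: int,
    n_scaffolds: int = 3,
    region: int = 20_000,
) -> AnnotationSet:
    """Random annotation with overlapping genes, so nesting arises naturally."""
    genes = []
    for i in range(n_genes):
        scaffold = f"s{int(rng.integers(n_scaffolds))}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(1, 4))
        pos = int(rng.integers(0, region))
        coords = []
        for _ in range(k):
            elen = int(rng.integers(10, 120))
            coords.append((pos, pos + elen))
            pos += elen + int(rng.integers(1, 600))
        genes.append(make_gene(f"g{i:04d}", scaffold, coords, strand))
    return AnnotationSet(genes)


def brute_force_nested_ids(ann: AnnotationSet) -> set[str]:
    """All-pairs containment oracle for nested-gene detection."""
    nested = set()
    for g in ann:
        for h in ann:
            if g.id == h.id or g.scaffold != h.scaffold:
                continue
            for tx in h.transcripts:
                for intr in tx.introns:
                    if intr.start <= g.span.start and g.span.end <= intr.end:
                        nested.add(g.id)
    return nested


def hypergeom_p_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by direct hypergeometric tail sum."""
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(n_total, col1)
    hi = min(row1, col1)
    return sum(
        math.comb(row1, x) * math.comb(n_total - row1, col1 - x)
        for x in range(a, hi + 1)
    ) / denom


def collinear_runs(perm: list[int], min_block: int) -> list[tuple[list[int], int]]:
    """Maximal runs of +-1 steps in a permutation (block oracle at max_gap 0).

    Returns (query ordinals of the run, direction) for runs >= min_block.
    """
    runs: list[tuple[list[int], int]] = []
    run = [0]
    direction = 0
    for i in range(1, len(perm)):
        step = perm[i] - perm[i - 1]
        if abs(step) == 1 and direction in (0, step):
            run.append(i)
            direction = step
        else:
            runs.append((run, direction))
            run, direction = [i], 0
    runs.append((run, direction))
    return [r for r in runs if len(r[0]) >= min_block]


def oracle_weighted_rank_order(table, scheme) -> list[str]:
    """Independent weighted Sigma-rank computation (counting-based ranks)."""
    scores = {}
    for asm in table.index:
        total = 0.0
        for metric, spec in scheme.items():
            values = table[metric].astype(float)
            v = values[asm]
            if spec.direction == "higher_better":
                better = int((values > v).sum())
            else:
                better = int((values < v).sum())
            equal = int((values == v).sum())
            rank = better + (equal + 1) / 2.0
            total += spec.weight * rank
        scores[asm] = total
    return sorted(table.index, key=lambda a: (scores[a], str(a)))


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
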