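"""Biomineralization-candidate screening by amino-acid compositional bias.

Mineral-scaffold proteins (glassin-like histidine-rich proteins, silaffins,
shell-matrix proteins) are typically low-complexity and escape homology
search; they can instead be found by comparing each protein's amino-acid
frequencies against a reference proteome.  A protein is flagged when the
frequency of any residue reaches that residue's high percentile (default
99th) over the reference.  Flagged proteins are narrowed to candidates by
requiring bias in the mineralization-associated residues D/E/H/P/S/T and
significant differential expression in the growth zone.  A cathepsin-L
style cleavage scan ([V/L]G'G, cut between the glycines) and average-mass
fragment prediction support maturation-size hypotheses.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import ExpressionRecord, SequenceSet

#: the 20 standard amino acids, alphabetical
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: average (isotope-abundance-weighted) residue masses in Da, ExPASy values
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153  # Da, added once per chain

#: residues recurrently enriched in biomineralization scaffold proteins
BIOMIN_RESIDUES = frozenset("DEHPST")


@dataclass(frozen=True)
class CompositionVector:
    protein: str
    length: int  # standard residues counted
    freq: dict[str, float]  # all 20 standard residues, sums to 1


@dataclass(frozen=True)
class PercentileTable:
    q: float
    values: dict[str, float]  # residue -> q-th percentile frequency
    reference_size: int
    min_len: int


@dataclass(frozen=True)
class BiasRecord:
    protein: str
    flagged: bool
    biased_aas: frozenset[str]
    freq: dict[str, float]


@dataclass(frozen=True)
class BiasReport:
    records: dict[str, BiasRecord]
    min_len: int

    @property
    def flagged_ids(self) -> list[str]:
        return sorted(pid for pid, r in self.records.items() if r.flagged)


@dataclass(frozen=True)
class Candidate:
    protein: str
    biased_aas: frozenset[str]  # intersection with the allowed residue set
    log2fc: float
    padj: float


@dataclass(frozen=True)
class CandidateList:
    candidates: tuple[Candidate, ...]
    allowed: frozenset[str]
    padj_max: float
    direction: str


@dataclass(frozen=True)
class CleavageResult:
    protein: str
    sites: tuple[int, ...]  # cut positions (sequence index of the second G)
    fragments: tuple[str, ...]
    fragment_masses_kda: tuple[float, ...]


def _clean(seq: str) -> str:
    return seq.rstrip("*").upper()


def aa_composition(seq: str, protein_id: str = "") -> CompositionVector:
    """Amino-acid frequencies over the 20 standard residues.

    Non-standard residues (X, B, Z, U, ...) are excluded from both the
    numerator and the denominator; a trailing stop symbol is stripped.
    """
    seq = _clean(seq)
    counts = {aa: seq.count(aa) for aa in STANDARD_AA}
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            f"protein {protein_id!r} has no standard residues after filtering"
        )
    return CompositionVector(
        protein=protein_id,
        length=total,
        freq={aa: counts[aa] / total for aa in STANDARD_AA},
    )


def _freq_matrix(seqs: SequenceSet, min_len: int) -> tuple[list[str], np.ndarray]:
    """Frequency matrix (proteins x 20) over proteins with >= min_len
    standard residues."""
    ids = []
    rows = []
    for pid in seqs:
        comp = aa_composition(seqs[pid], pid)
        if comp.length < min_len:
            continue
        ids.append(pid)
        rows.append([comp.freq[aa] for aa in STANDARD_AA])
    return ids, np.asarray(rows, dtype=float)


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (ceiling) percentile: the value at rank ceil(q/100 * n)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q / 100.0 * n))
    return float(v[min(rank, n) - 1])


def reference_percentiles(
    reference: SequenceSet, q: float = 99.0, min_len: int = 50
) -> PercentileTable:
    """Per-residue q-th percentile of per-protein frequency over a reference
    proteome (any large proteome FASTA, e.g. SwissProt, may serve)."""
    ids, freqs = _freq_matrix(reference, min_len)
    if len(ids) < 100:
        raise ValueError(
            f"reference has only {len(ids)} proteins of >= {min_len} residues; "
            "need at least 100"
        )
    values = {
        aa: nearest_rank_percentile(freqs[:, j], q)
        for j, aa in enumerate(STANDARD_AA)
    }
    return PercentileTable(q=q, values=values, reference_size=len(ids), min_len=min_len)


def flag_biased_proteins(
    proteome: SequenceSet, table: PercentileTable, min_len: int = 50
) -> BiasReport:
    """Flag proteins whose frequency of any residue reaches the reference
    percentile.  Proteins shorter than *min_len* are never flagged."""
    records: dict[str, BiasRecord] = {}
    for pid in proteome:
        comp = aa_composition(proteome[pid], pid)
        if comp.length < min_len:
            records[pid] = BiasRecord(pid, False, frozenset(), comp.freq)
            continue
        biased = frozenset(
            aa for aa in STANDARD_AA if comp.freq[aa] >= table.values[aa]
        )
        records[pid] = BiasRecord(pid, bool(biased), biased, comp.freq)
    return BiasReport(records=records, min_len=min_len)


def select_candidates(
    report: BiasReport,
    expr: Sequence[ExpressionRecord],
    allowed: frozenset[str] = BIOMIN_RESIDUES,
    padj_max: float = 1e-4,
    direction: str = "up",
) -> CandidateList:
    """Narrow flagged proteins to expression-supported candidates.

    Keeps proteins biased in at least one allowed residue, with adjusted
    p-value at most *padj_max* and fold-change in *direction*.  Flagged
    proteins absent from the expression table are excluded with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    by_gene = {rec.gene: rec for rec in expr}
    out: list[Candidate] = []
    unscored: list[str] = []
    for pid in report.flagged_ids:
        rec = report.records[pid]
        overlap = rec.biased_aas & allowed
        if not overlap:
            continue
        erec = by_gene.get(pid)
        if erec is None:
            unscored.append(pid)
            continue
        if erec.padj is None or erec.padj > padj_max:
            continue
        if direction == "up" and erec.log2fc <= 0:
            continue
        if direction == "down" and erec.log2fc >= 0:
            continue
        out.append(Candidate(pid, overlap, erec.log2fc, erec.padj))
    if unscored:
        warnings.warn(
            f"{len(unscored)} flagged proteins lacked expression records and were "
            f"excluded (first: {unscored[0]})",
            stacklevel=2,
        )
    out.sort(key=lambda c: (c.padj, c.protein))
    return CandidateList(
        candidates=tuple(out),
        allowed=frozenset(allowed),
        padj_max=padj_max,
        direction=direction,
    )


_CLEAVAGE_RE = re.compile(r"(?=([VL]GG))")


def scan_cleavage_sites(seq: str, protein_id: str = "") -> CleavageResult:
    """Scan for the cathepsin-L-style [V/L]G'G motif and cut the chain.

    Each match yields a cut between the two glycines; overlapping matches
    are all reported.  Fragments concatenate back to the input, and each
    fragment's average mass is predicted in kDa.
    """
    seq = _clean(seq)
    cuts = sorted(m.start() + 2 for m in _CLEAVAGE_RE.finditer(seq))
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(seq[a:b] for a, b in zip(bounds, bounds[1:]))
    masses = tuple(predict_mass(f) for f in fragments)
    return CleavageResult(
        protein=protein_id,
        sites=tuple(cuts),
        fragments=fragments,
        fragment_masses_kda=masses,
    )


def predict_mass(fragment: str) -> float:
    """Average molecular mass of a peptide in kDa (residue masses + one water).

    Average rather than monoisotopic masses are used, matching SDS-PAGE
    scale comparisons.  Non-standard residues are an error.
    """
    fragment = _clean(fragment)
    if not fragment:
        raise ValueError("cannot predict mass of an empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(fragment):
        mass = AVERAGE_RESIDUE_MASS.get(aa)
        if mass is None:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
        total += mass
    return total / 1000.0
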