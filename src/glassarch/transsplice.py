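"""Spliced-leader (SL) trans-splicing detection from long-read alignments.

A trans-spliced leader is a short RNA added to the 5' end of mRNAs; when
full-length cDNA reads are aligned to the genome the leader cannot map and
appears as a soft-clipped prefix (CIGAR ``S`` at the transcript's 5' end).
This module extracts those clips strand-aware, builds the clip-length
histogram with windowed peak detection, and derives the leader consensus
and frequency statistics.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import reverse_complement

from .model import AlignedRead, FormatParseError


@dataclass(frozen=True)
class ClipEvent:
    """One 5'-of-transcript soft clip.

    ``clip_seq`` is oriented 5'->3' in transcript orientation; its last
    base is adjacent to the first aligned base.
    """

    read: str
    scaffold: str
    clip_length: int
    clip_seq: Optional[str]
    strand: str


@dataclass(frozen=True)
class ClipHistogram:
    counts: dict[int, int]  # clip length -> read count
    window: tuple[int, int]
    peak_length: Optional[int]  # modal length within window; ties -> smaller


@dataclass(frozen=True)
class LeaderMotif:
    consensus: str
    consensus_length: int
    leader_read_fraction: float  # qualifying clips / total mapped reads
    top_leader_share: float  # most common exact clip / qualifying clips
    n_qualifying: int


def _five_prime_softclip(read: AlignedRead) -> Optional[tuple[int, Optional[str]]]:
    """Length and sequence of the transcript-5' soft clip, if any.

    Plus-strand reads: a leading S op (after any outer hard clip).  Minus
    strand: a trailing S op, whose sequence is reverse-complemented into
    transcript orientation.  Hard clips never yield sequence.
    """
    cigar = read.cigar
    if not cigar:
        return None
    if read.strand == "+":
        idx = 1 if cigar[0][1] == "H" and len(cigar) > 1 else 0
        length, op = cigar[idx]
        if op != "S":
            return None
        seq = read.query_seq[:length] if read.query_seq is not None else None
        return length, seq
    idx = -2 if cigar[-1][1] == "H" and len(cigar) > 1 else -1
    length, op = cigar[idx]
    if op != "S":
        return None
    if read.query_seq is None:
        return length, None
    seq = reverse_complement(read.query_seq[-length:])
    return length, seq


def extract_clips(
    reads: Sequence[AlignedRead], min_len: int = 20, max_len: int = 60
) -> list[ClipEvent]:
    """Extract transcript-5' soft-clip events within [min_len, max_len]."""
    events: list[ClipEvent] = []
    for read in reads:
        got = _five_prime_softclip(read)
        if got is None:
            continue
        length, seq = got
        if read.query_seq is not None and length > len(read.query_seq):
            raise FormatParseError(
                f"read {read.name}: soft clip {length} exceeds query length"
            )
        if not (min_len <= length <= max_len):
            continue
        events.append(
            ClipEvent(
                read=read.name,
                scaffold=read.scaffold,
                clip_length=length,
                clip_seq=seq,
                strand=read.strand,
            )
        )
    return events


def clip_histogram(
    events: Sequence[ClipEvent], window: tuple[int, int] = (20, 60)
) -> ClipHistogram:
    """Integer-binned clip-length histogram with a windowed modal peak."""
    counts = Counter(ev.clip_length for ev in events)
    lo, hi = window
    in_window = {l: c for l, c in counts.items() if lo <= l <= hi}
    peak = None
    if in_window:
        best = max(in_window.values())
        peak = min(l for l, c in in_window.items() if c == best)
    return ClipHistogram(counts=dict(sorted(counts.items())), window=window, peak_length=peak)


def leader_consensus(
    events: Sequence[ClipEvent],
    peak: int,
    tolerance: int = 3,
    total_mapped: int = 0,
) -> LeaderMotif:
    """Consensus leader from clips near the peak length.

    Clips with length within *tolerance* of *peak* are aligned at their 3'
    (alignment-adjacent) ends, because partially degraded leaders present
    ragged 5' ends but a fixed junction.  The consensus is the per-position
    majority base over the peak-length window (ties broken alphabetically).
    """
    if total_mapped < 0:
        raise ValueError("total_mapped must be >= 0")
    qualifying = [
        ev.clip_seq
        for ev in events
        if ev.clip_seq is not None
        and peak - tolerance <= ev.clip_length <= peak + tolerance
    ]
    if not qualifying:
        raise ValueError(
            f"no soft-clip sequences within {tolerance} bp of peak {peak}; "
            "insufficient evidence for a leader consensus"
        )
    consensus_chars = []
    for offset in range(peak, 0, -1):  # 5' -> 3' over the peak-length window
        bases = Counter(seq[-offset] for seq in qualifying if len(seq) >= offset)
        best = max(bases.values())
        consensus_chars.append(min(b for b, c in bases.items() if c == best))
    consensus = "".join(consensus_chars)
    top_count = max(Counter(qualifying).values())
    return LeaderMotif(
        consensus=consensus,
        consensus_length=len(consensus),
        leader_read_fraction=(len(qualifying) / total_mapped) if total_mapped else 0.0,
        top_leader_share=top_count / len(qualifying),
        n_qualifying=len(qualifying),
    )
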