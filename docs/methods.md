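# Methods

This note documents the models and procedures implemented in `glassarch`,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions that make
results deterministic.

## Coordinate model

All internal coordinates are 0-based half-open intervals; GFF3 I/O converts
to and from 1-based inclusive coordinates at the boundary and nowhere else.
A gene's span is the union envelope over all of its isoforms, so statements
about a gene's position (e.g. "nested in an intron") hold for every
isoform. Duplicate gene identifiers are a fatal error rather than being
merged: silent deduplication would corrupt gene order, on which the whole
microsynteny stage depends. Transcript rows may be typed `mRNA` or
`transcript` (BRAKER2 and StringTie dialects). Alignments are consumed as
text SAM through pysam; secondary and supplementary records are skipped by
default so each read contributes exactly once to totals.

## Nested genes

Gene *G* is nested in host *H* iff both are on one scaffold, *G* ≠ *H*, and
*G*'s span lies entirely within a single intron of at least one transcript
of *H*. Strand is deliberately ignored (a `require_opposite_strand`-style
restriction can be applied downstream by filtering the reported pairs on
gene strands); genes overlapping any host exon are not nested, which is the
strictest unambiguous reading of "contained in an intron". A nested gene is
counted once even when several hosts or host isoforms contain it; all
(gene, host, transcript, intron) relations are listed. Two fractions are
reported: nested genes / all genes, and exonic bp of nested genes / total
exonic bp, both using per-gene exon unions. The detector is validated by
exact set-equality against a brute-force all-pairs containment oracle on
hundreds of randomised annotations, and by exact recovery of planted
fractions f ∈ {0, 0.05, 0.12}.

## Bulk statistics, intron profiles, contiguity, contaminant screen

Mean gene length uses the gene span; mean transcript length uses summed
exon length (the convention under which orthologous transcripts of two
compact genomes are comparable even when intron content differs). Intron
counts in bulk statistics are per transcript; the per-scaffold *intron
profile* instead deduplicates introns by exact (start, end), since shared
splice sites across isoforms would otherwise double-count, and reports
lengths sorted descending for profile plots.

N50 is the length of the sequence at which the descending cumulative sum
first reaches half the total; ties resolve toward the larger scaffold. The
N50/total ratio is reported because it is scale-free: a chromosome-level
assembly of a typical (10–30 chromosome) animal genome sits around 0.02 or
higher. Threshold statistics (`scaffolds_over_threshold`) use strict `>`
on raw lengths, and the fraction is a basepair fraction.

The contaminant screen flags a scaffold when GC fraction exceeds a
threshold (default 0.40) AND mean RNA coverage falls below a threshold
(default 1×): bacterial DNA in an animal assembly is GC-rich relative to an
AT-rich host and recruits essentially no poly-A-selected RNA reads. GC is
computed over unambiguous A/C/G/T only so assembly gaps (N runs) do not
dilute it. The full table is emitted regardless of flags for blob-style
inspection.

## Microsynteny

High-copy families are removed before anchor building: any protein (on
either side) participating in more than `max_hits` (default 50) retained
hits is dropped together with all of its hits, with sweeps iterated to a
fixed point. This prevents parallel family expansions and transposons from
producing spurious cross-scaffold matches. Anchors are best-hit-per-query
(max bitscore, ties by smaller e-value then lexicographic subject id);
reciprocal-best filtering can be layered on by intersecting the two
directions.

Chaining is greedy left-to-right within each scaffold pair, scanning
anchors by query ordinal. An anchor extends the open chain when both
ordinal steps are in [1, max_gap + 1] — i.e. at most `max_gap` genes are
skipped on either genome — and the subject step continues the chain's
direction; the default `max_gap` = 5 tolerates interleaved
lineage-specific insertions (tandem expansions commonly interrupt otherwise
collinear runs) without breaking blocks. Chains of ≥ `min_block` (default
3) anchors become blocks; each anchor belongs to at most one block. A
consequence of gap tolerance worth knowing: an inverted segment shorter
than `max_gap` + 2 can be partially absorbed by the flanking forward
chain, so tests of exact planted-structure recovery use either
`max_gap` = 0 or inversions longer than the gap window.

Scaffold-pair significance uses Fisher's exact test on the 2×2 table
(a = hits between the pair, b = other hits from the query scaffold,
c = other hits to the subject scaffold, d = all remaining hits), one-sided
toward enrichment — the only meaningful direction here — with
Benjamini–Hochberg adjustment across all tested pairs. Pairs with zero
hits are not tested, so vacuous p = 1 rows never inflate the BH
denominator. Correctness is checked against an independent hypergeometric
tail enumeration: exhaustively for all tables with N ≤ 30 (≈ 46 000
tables) and on 1500 seeded random tables with N ≤ 200, at 1e-12; the
closed case (2,0,0,2) gives p = 1/6. (Full enumeration of every table up
to N = 200 would be ~7×10⁷ Fisher evaluations; the exhaustive-plus-sampled
design covers the same argument at practical cost.)

Tandem clusters: same-family genes on one scaffold are merged when
consecutive member-to-member ordinal gaps are ≤ `max_interleave` + 1
(default tolerating 3 interleaved genes), and clusters of ≥ `min_cluster`
(default 3) members are reported with their interleaved-gene counts.

## Trans-spliced leaders

Only soft clips (`S`) yield leader candidates — hard clips carry no
sequence. The transcript-5′ clip is the leading `S` on plus-strand reads
and the trailing `S` on minus-strand reads, reverse-complemented into
transcript orientation; 5′-ness is determined from alignment strand alone,
which assumes full-length, correctly oriented cDNA reads (stranded
long-read cDNA protocols). Clips are windowed to [20, 60] bp by default,
bracketing the length regime reported for animal spliced leaders. The
histogram peak is the windowed mode, ties toward the smaller length.

The consensus is anchored at the clips' 3′ (alignment-adjacent) ends,
because partially degraded leaders present ragged 5′ ends but a fixed
splice junction; per-position majority over the peak-length window, with
base ties broken alphabetically, makes the output deterministic. Reported
statistics: leader_read_fraction = qualifying clips (within ±tolerance of
the peak, default 3 bp) / all mapped reads, and top_leader_share = most
frequent exact clip string / qualifying clips. For a per-base error rate e
and n leader reads, the majority consensus at a position fails with
probability ≤ exp(−2n(1/2 − e)²); at e = 0.05 and n ≥ 200 exact recovery
is essentially certain, which the seeded simulations confirm.

## Compositional-bias screen

Per-protein amino-acid frequencies are computed over the 20 standard
residues; non-standard residues are excluded from numerator and
denominator, and a trailing stop symbol is stripped. The reference table is
the per-residue empirical q-th percentile (default 99) of those
frequencies over a reference proteome, using the nearest-rank (ceiling)
convention for determinism; any large proteome FASTA may serve as the
reference. A protein is flagged when its frequency of any residue reaches
that residue's table value. A minimum length of 50 residues gates both the
reference and the screen: shorter sequences have degenerate compositions
that would dominate the flag list.

By the nearest-rank convention, self-screening a reference against its own
P99 table flags slightly over 1% per residue (the value at rank ⌈0.99 n⌉
plus anything tied with it); with continuously varying synthetic
frequencies the rate stays within 1% ± 0.5% at n = 10 000, which is the
calibration the tests assert.

Candidate narrowing keeps flagged proteins whose biased residues intersect
D/E/H/P/S/T (the residues recurrently enriched in biomineralization
scaffold proteins across animals and diatoms), with adjusted p ≤ 1e-4 and
fold-change in the requested direction (default up, i.e. higher in the
growth zone). The differential-expression table is consumed as input — the
DE model itself is out of scope. Flagged proteins missing from the table
are excluded with a warning rather than silently passed or failed.

Cleavage scanning finds every (overlapping) match of [V or L]-G-G and cuts
between the two glycines; fragments concatenate exactly to the input and
each fragment's mass is the sum of average (isotope-weighted) residue
masses plus one water (18.0153 Da), reported in kDa. Average rather than
monoisotopic masses match SDS-PAGE-scale size comparisons. Mass additivity
(sum of fragment masses = whole-chain mass + one water per cut) holds to
1e-6 kDa and is asserted on 1000 random proteins.

## Assembly ranking

Assemblies are ranked per metric (1 = best, average ranks on ties — ties
must not depend on row order), with a per-metric optimisation direction,
and combined as a weighted rank sum; the smallest score wins, residual
ties broken lexicographically by id. The default scheme carries the seven
standard evaluation metrics (N50 ↑, percent size delta to the predicted
genome size ↓, mean scaffold length ↑, scaffold count ↓, BUSCO single-copy
complete ↑, RNA mapping % ↑, DNA mapping % ↑) at unit weights; weights are
a configuration input (YAML) because relative importances are a project
decision, not a property of the data. Rank aggregation is invariant to
monotone transformations of any metric and to zero-weight metrics, both of
which are property-tested against a counting-based oracle.

## Synthetic-data generators

All generators take an explicit seed and are byte-deterministic per seed.

- **Annotated genome**: top-level genes are packed left-to-right without
  overlap (lognormal exon/intron/intergenic lengths: medians ≈ 160 bp,
  300 bp and 500 bp; the intron median sits between the two regimes seen
  in compact genomes, roughly 200–500 bp); a configurable fraction of
  transcripts is single-exon (default 0.30). Planted nested genes are
  always single-exon (as glassin is) and strictly interior to one host
  intron with ≥ 10 bp margins, so detector recovery is exact and separates
  detector correctness from definitional edge cases; the
  `single_exon_fraction` parameter therefore governs top-level genes.
  Contaminant scaffolds carry no genes, GC 0.55 versus the 0.36 host
  background, and zero RNA coverage. Packing that exceeds the configured
  scaffold space is an error rather than a silent stretch.
- **Ortholog pair**: genome B's order is genome A's order partitioned onto
  B scaffolds with planted inversions (validated disjoint and within one
  scaffold), lineage-specific insertions at a configurable rate, and an
  optional interleaved tandem family planted in genome A. Ortholog hits
  carry bitscores in [300, 600]; paralog/spurious noise stays below 250, so
  best-hit reduction recovers the planted map exactly — noise robustness is
  tested through recall bounds, not by overlapping score ranges.
- **Leader reads**: full-length cDNA alignments written as text SAM;
  leader-bearing reads (default 4%, leader 37 bp) have the leader
  prepended and soft-clipped, minus-strand records carry
  reference-forward SEQ with a trailing `S`, exactly as an aligner emits
  them; substitution errors (default regimes 0–5%) apply to leader and
  aligned bases alike. No indel or homopolymer error model is included, so
  clip lengths are exact; real long-read data would spread the histogram
  around the peak rather than concentrating it.
- **Proteome**: background compositions are per-protein Dirichlet draws
  around database-like residue frequencies (so per-protein frequencies
  vary continuously and ties in the percentile table are rare); planted
  proteins (default 2%) exceed the reference P99 of one D/E/H/P/S/T
  residue by a 0.05 margin *by construction*, and receive strong planted
  upregulation (log2FC ≈ 5) with adjusted p in [1e-10, 1e-5]; background
  adjusted p-values are uniform. P-values are generated directly rather
  than through a count model, since DE fitting is out of scope.
- **Assembly metrics**: random plausible metric values; in dominating mode
  one assembly is strictly best on every metric and recorded as truth.

Because generators emulate structure, not sequencing physics, passing
tests demonstrate correctness of the detectors' logic and calibration of
their statistics under the stated assumptions — they do not demonstrate
robustness to annotation errors, mapping artefacts, indel-rich reads, or
genuinely ambiguous nesting, which real data contain.

## Problem sizes and determinism of the verification suite

The test suite and `scripts/acceptance.py` run the detectors at these
sizes: 200 random annotations of ≤ 200 genes for nested-oracle
equivalence; a 2000-gene genome at planted fraction 0.12; 200-gene
ortholog pairs with two planted inversions; exhaustive 2×2 enumeration to
N = 30 plus 1500 random tables to N = 200; 5000 reads at the 4%/37 bp/5%
regime; a 10 000-protein reference for screen calibration; 1000 random
proteins for cleavage-mass additivity; and 20 random 7-assembly tables for
rank aggregation. All randomness flows through explicit seeds; the
acceptance script derives per-stage seeds from its `--seed` argument.
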