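# glassarch

Genome-architecture and biomineralization-candidate analyses for compact
animal genomes, motivated by glass sponges (Hexactinellida) — organisms with
small, gene-dense genomes, an unusually high share of *nested genes*, strong
microsynteny between species, spliced-leader trans-splicing, and
low-complexity silica-scaffold proteins (glassin and relatives) that escape
ordinary homology search.

The package is a tested, reusable re-implementation of the bespoke analyses
such a genome project needs, together with seeded synthetic-data generators
so the whole pipeline is verifiable without any external downloads.

## What it computes

- **Nested genes** (`glassarch.architecture`): gene *G* is nested in host
  *H* iff both lie on the same scaffold and *G*'s span (the union envelope
  over isoforms) falls entirely within a single intron of at least one
  transcript of *H*; strand is ignored. Reports counts, the nested fraction
  of genes, and the nested fraction of exonic basepairs, plus bulk
  annotation statistics and per-scaffold unique-intron profiles.
- **Assembly contiguity**: N50 (descending cumulative sum first reaching
  ≥ half the total) and the N50/total-length ratio, a scale-free indicator
  of closeness to chromosome level (≈ 0.02 and above for chromosome-scale
  assemblies), plus a GC > threshold ∧ RNA-coverage < threshold screen for
  bacterial contaminant scaffolds.
- **Microsynteny** (`glassarch.microsynteny`): iterative removal of
  high-copy families (> 50 hits by default), best-hit-per-query anchor
  reduction, greedy collinear chaining into blocks of ≥ 3 genes with a
  configurable gap tolerance, per-scaffold-pair enrichment by one-sided
  Fisher's exact test on the 2×2 table
  (hits between the pair | other hits from the query scaffold | other hits
  to the subject scaffold | all remaining hits) with Benjamini–Hochberg
  correction, dot-plot export, syntenic/non-syntenic gene classification,
  and interleaved tandem-cluster detection.
- **Trans-spliced leaders** (`glassarch.transsplice`): strand-aware
  extraction of transcript-5′ soft clips (CIGAR `S`) from long-read
  alignments, clip-length histogram with windowed peak detection, and a
  3′-anchored majority consensus with leader-frequency statistics.
- **Compositional-bias screen** (`glassarch.biomin_screen`): per-protein
  amino-acid frequencies against a reference proteome's per-residue 99th
  percentile (nearest-rank); candidate narrowing by bias in the
  mineralization-associated residues D/E/H/P/S/T plus significant
  differential expression; cathepsin-L-style `[V/L]G′G` cleavage scanning
  with average-mass fragment prediction.
- **Assembly selection** (`glassarch.assembly_select`): weighted rank
  aggregation over a metric table (N50, size delta, scaffold counts, BUSCO,
  read-mapping rates), average ranks on ties, smallest weighted rank sum
  wins.
- **Synthetic data** (`glassarch.synthetic_data`): deterministic, seeded
  generators for each of the above, with ground-truth bundles.

## Worked example

Simulate a compact 2000-gene genome with 12% of genes planted inside host
introns, then detect them:

```sh
$ glassarch simulate genome --seed 11 --genes 2000 --nested-fraction 0.12 --out demo
genes=2000
nested_planted=240

$ glassarch nested --gff demo/annotation.gff3
nested_genes=240
total_genes=2000
nested_fraction=0.1200
nested_exonic_fraction=0.0421
```

All 240 planted nested genes are recovered (12.0% of genes; they hold 4.2%
of exonic basepairs). Contiguity of the simulated assembly:

```sh
$ glassarch contiguity --fasta demo/genome.fasta --threshold 300000
total_length=5600000
scaffold_count=14
n50=400000
n50_over_total=0.0714
```

Spliced-leader discovery from simulated long reads (4% of 2000 reads carry
a 37 bp leader; 5% per-base error):

```sh
$ glassarch simulate reads --seed 11 --reads 2000 --leader-fraction 0.04 \
      --error-rate 0.05 --out demo
$ glassarch transsplice --sam demo/reads.sam
mapped_reads=2000
clip_events=92
peak_length=37
consensus=ATTCTATTTCGGTGTACTGGTTCCCTGACCAATTTTG
leader_read_fraction=0.0460
top_leader_share=0.1304
```

The clip-length histogram peaks at the planted leader length, the majority
consensus reconstructs the leader exactly despite the 5% error rate, and
the estimated leader-bearing fraction (4.6%) matches the simulated 4%
within binomial noise. Other subcommands: `glassarch synteny
blocks|test|dotplot`, `glassarch compbias`, `glassarch cleave`,
`glassarch rank`, `glassarch screen`, `glassarch simulate ...`
(see `--help` on each).

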