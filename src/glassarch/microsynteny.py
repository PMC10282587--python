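"""Microsynteny between two annotated genomes.

Gene order is reduced to per-scaffold ordinals; one-to-one anchors (best
hit per query) are chained greedily into collinear blocks; scaffold-pair
enrichment is assessed with a one-sided Fisher's exact test on the 2x2
table (hits between the pair / from the query scaffold elsewhere / to the
subject scaffold from elsewhere / all remaining hits), with
Benjamini-Hochberg correction across tested pairs.  High-copy families
are removed beforehand so parallel expansions do not produce spurious
matches.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from scipy.stats import false_discovery_control, fisher_exact

from .model import AnnotationSet, Hit, HitTable


@dataclass(frozen=True)
class GeneOrder:
    """Per-scaffold gene order: ordinal 0 is the leftmost gene by span start."""

    orders: dict[str, tuple[str, ...]]
    index: dict[str, tuple[str, int]]  # gene id -> (scaffold, ordinal)

    def scaffold_of(self, gene_id: str) -> str:
        return self.index[gene_id][0]

    def ordinal_of(self, gene_id: str) -> int:
        return self.index[gene_id][1]


@dataclass(frozen=True)
class SyntenyBlock:
    scaffold_a: str
    scaffold_b: str
    anchors: tuple[tuple[str, str], ...]  # (gene_a id, gene_b id)
    orientation: str  # "+" or "-"

    @property
    def size(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class PairTest:
    scaffold_a: str
    scaffold_b: str
    a: int  # hits between the pair
    b: int  # hits from scaffold_a elsewhere
    c: int  # hits to scaffold_b from elsewhere
    d: int  # all remaining hits
    p: float
    p_adj: float


@dataclass(frozen=True)
class TandemCluster:
    scaffold: str
    family: str
    members: tuple[str, ...]  # gene ids in ordinal order
    span: tuple[int, int]  # first and last member ordinal (inclusive)
    interleaved_count: int  # non-member genes inside the ordinal range

    @property
    def size(self) -> int:
        return len(self.members)


def filter_high_copy_hits(hits: HitTable, max_hits: int = 50) -> HitTable:
    """Remove high-copy proteins (either side) together with all their hits.

    Any protein participating in more than *max_hits* retained hits is
    dropped; removal is iterated until no protein exceeds the cutoff, so
    the output is a fixed point.
    """
    if max_hits < 1:
        raise ValueError(f"max_hits must be >= 1, got {max_hits}")
    current = list(hits)
    while True:
        q_counts = Counter(h.query for h in current)
        s_counts = Counter(h.subject for h in current)
        bad_q = {q for q, c in q_counts.items() if c > max_hits}
        bad_s = {s for s, c in s_counts.items() if c > max_hits}
        if not bad_q and not bad_s:
            break
        current = [
            h for h in current if h.query not in bad_q and h.subject not in bad_s
        ]
    return HitTable(tuple(current))


def build_gene_order(ann: AnnotationSet) -> GeneOrder:
    """Per-scaffold ordinals by span start (ties broken by gene id)."""
    orders: dict[str, tuple[str, ...]] = {}
    index: dict[str, tuple[str, int]] = {}
    for scaffold in ann.scaffolds():
        ids = tuple(g.id for g in ann.genes_on(scaffold))
        orders[scaffold] = ids
        for ordinal, gid in enumerate(ids):
            index[gid] = (scaffold, ordinal)
    return GeneOrder(orders=orders, index=index)


def best_hit_per_query(hits: HitTable) -> HitTable:
    """Reduce to one hit per query: max bitscore, then min evalue, then
    lexicographically smallest subject id."""
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None:
            best[h.query] = h
            continue
        if (-h.bitscore, h.evalue, h.subject) < (-cur.bitscore, cur.evalue, cur.subject):
            best[h.query] = h
    return HitTable(tuple(best[q] for q in sorted(best)))


def detect_synteny_blocks(
    anchor_hits: HitTable,
    order_a: GeneOrder,
    order_b: GeneOrder,
    min_block: int = 3,
    max_gap: int = 5,
) -> list[SyntenyBlock]:
    """Chain collinear anchors greedily into synteny blocks.

    Within each scaffold pair, anchors are scanned in query-ordinal order.
    An anchor extends the open chain when both ordinal steps skip at most
    *max_gap* genes (step size in [1, max_gap + 1]) and the subject step
    continues the chain's direction; otherwise the chain closes and a new
    one starts.  Chains of at least *min_block* anchors become blocks, so
    each anchor belongs to at most one block.
    """
    seen_queries: set[str] = set()
    per_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = defaultdict(list)
    for h in anchor_hits:
        if h.query in seen_queries:
            raise ValueError(
                f"query {h.query} has multiple anchors; reduce with best_hit_per_query"
            )
        seen_queries.add(h.query)
        if h.query not in order_a.index:
            raise KeyError(f"anchor gene {h.query!r} not in query gene order")
        if h.subject not in order_b.index:
            raise KeyError(f"anchor gene {h.subject!r} not in subject gene order")
        sc_a, oa = order_a.index[h.query]
        sc_b, ob = order_b.index[h.subject]
        per_pair[(sc_a, sc_b)].append((oa, ob, h.query, h.subject))

    blocks: list[SyntenyBlock] = []

    def _close(pair, chain, direction) -> None:
        if len(chain) < min_block:
            return
        orientation = "+" if (direction is None or direction > 0) else "-"
        blocks.append(
            SyntenyBlock(
                scaffold_a=pair[0],
                scaffold_b=pair[1],
                anchors=tuple((qa, qb) for _, _, qa, qb in chain),
                orientation=orientation,
            )
        )

    max_step = max_gap + 1
    for pair in sorted(per_pair):
        anchors = sorted(per_pair[pair])
        chain = [anchors[0]]
        direction: Optional[int] = None
        for anc in anchors[1:]:
            last = chain[-1]
            a_step = anc[0] - last[0]
            b_step = anc[1] - last[1]
            sign = 1 if b_step > 0 else -1
            ok = (
                1 <= a_step <= max_step
                and 1 <= abs(b_step) <= max_step
                and (direction is None or sign == direction)
            )
            if ok:
                chain.append(anc)
                if direction is None:
                    direction = sign
            else:
                _close(pair, chain, direction)
                chain = [anc]
                direction = None
        _close(pair, chain, direction)
    return blocks


def scaffold_pair_significance(
    hits: HitTable, order_a: GeneOrder, order_b: GeneOrder
) -> list[PairTest]:
    """One-sided Fisher's exact enrichment test for every scaffold pair.

    For each pair with at least one hit, the 2x2 table is (hits between the
    pair, other hits from the query scaffold, other hits to the subject
    scaffold, all remaining hits); p-values are BH-adjusted across all
    tested pairs.  Pairs with zero hits are not tested.
    """
    pair_counts: Counter = Counter()
    row_counts: Counter = Counter()
    col_counts: Counter = Counter()
    for h in hits:
        sc_a = order_a.index[h.query][0]
        sc_b = order_b.index[h.subject][0]
        pair_counts[(sc_a, sc_b)] += 1
        row_counts[sc_a] += 1
        col_counts[sc_b] += 1
    n = sum(pair_counts.values())

    pairs = sorted(pair_counts)
    raw_p: list[float] = []
    tables: list[tuple[int, int, int, int]] = []
    for sc_a, sc_b in pairs:
        a = pair_counts[(sc_a, sc_b)]
        b = row_counts[sc_a] - a
        c = col_counts[sc_b] - a
        d = n - a - b - c
        tables.append((a, b, c, d))
        raw_p.append(float(fisher_exact([[a, b], [c, d]], alternative="greater")[1]))
    if not pairs:
        return []
    adj = false_discovery_control(raw_p, method="bh")
    return [
        PairTest(sc_a, sc_b, *table, p=p, p_adj=min(float(pa), 1.0))
        for (sc_a, sc_b), table, p, pa in zip(pairs, tables, raw_p, adj)
    ]


def export_dotplot(
    hits: HitTable,
    order_a: GeneOrder,
    order_b: GeneOrder,
    path,
    plot_path=None,
) -> Path:
    """Write a dot-plot table (and optionally render a scatter plot).

    Each row is one gene match: (scaffold_a, ordinal_a, scaffold_b,
    ordinal_b, bitscore), in deterministic order.
    """
    rows = []
    for h in hits:
        sc_a, oa = order_a.index[h.query]
        sc_b, ob = order_b.index[h.subject]
        rows.append((sc_a, oa, sc_b, ob, h.bitscore))
    rows.sort()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("scaffold_a\tordinal_a\tscaffold_b\tordinal_b\tbitscore\n")
        for sc_a, oa, sc_b, ob, bits in rows:
            fh.write(f"{sc_a}\t{oa}\t{sc_b}\t{ob}\t{bits:.1f}\n")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        # cumulative ordinal offsets turn per-scaffold ordinals into one axis
        off_a = _cumulative_offsets(order_a)
        off_b = _cumulative_offsets(order_b)
        xs = [off_a[sc] + oa for sc, oa, _, _, _ in rows]
        ys = [off_b[sc] + ob for _, _, sc, ob, _ in rows]
        ax.scatter(xs, ys, s=4, color="black")
        ax.set_xlabel("gene position (query genome)")
        ax.set_ylabel("gene position (subject genome)")
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return path


def _cumulative_offsets(order: GeneOrder) -> dict[str, int]:
    offsets = {}
    cum = 0
    for scaffold in sorted(order.orders):
        offsets[scaffold] = cum
        cum += len(order.orders[scaffold])
    return offsets


def classify_syntenic_genes(
    blocks: list[SyntenyBlock], ann: AnnotationSet
) -> dict[str, str]:
    """Label each gene of *ann* syntenic (anchor of >= 1 block) or not."""
    anchored: set[str] = set()
    for blk in blocks:
        for ga, gb in blk.anchors:
            anchored.add(ga)
            anchored.add(gb)
    return {
        g.id: ("syntenic" if g.id in anchored else "non_syntenic") for g in ann
    }


def detect_tandem_clusters(
    ann: AnnotationSet,
    family_map: Mapping[str, str],
    min_cluster: int = 3,
    max_interleave: int = 3,
) -> list[TandemCluster]:
    """Find tandem gene-family clusters, tolerating interleaved genes.

    Same-family genes on one scaffold are merged into a cluster when each
    member-to-member ordinal gap is at most *max_interleave* + 1 (i.e. at
    most *max_interleave* unrelated genes sit between consecutive members).
    Clusters with at least *min_cluster* members are reported; unassigned
    genes never cluster.
    """
    order = build_gene_order(ann)
    clusters: list[TandemCluster] = []
    for scaffold in sorted(order.orders):
        ids = order.orders[scaffold]
        by_family: dict[str, list[int]] = defaultdict(list)
        for ordinal, gid in enumerate(ids):
            fam = family_map.get(gid)
            if fam is not None:
                by_family[fam].append(ordinal)
        for fam in sorted(by_family):
            ords = by_family[fam]
            run = [ords[0]]
            for o in ords[1:]:
                if o - run[-1] <= max_interleave + 1:
                    run.append(o)
                else:
                    _emit_cluster(clusters, scaffold, fam, run, ids, min_cluster)
                    run = [o]
            _emit_cluster(clusters, scaffold, fam, run, ids, min_cluster)
    return clusters


def _emit_cluster(clusters, scaffold, fam, run, ids, min_cluster) -> None:
    if len(run) < min_cluster:
        return
    first, last = run[0], run[-1]
    clusters.append(
        TandemCluster(
            scaffold=scaffold,
            family=fam,
            members=tuple(ids[o] for o in run),
            span=(first, last),
            interleaved_count=(last - first + 1) - len(run),
        )
    )
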