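"""Microsynteny: hit filtering, gene order, chaining, Fisher tests, tandems."""
import numpy as np
import pytest

from glassarch import microsynteny as ms
from glassarch.model import AnnotationSet, Hit, HitTable
from glassarch.synthetic_data import OrthoPairSimSpec, simulate_ortholog_pair

from conftest import collinear_runs, hypergeom_p_greater, make_gene


def hit(q, s, bits=100.0, evalue=1e-20):
    return Hit(q, s, 80.0, bits, evalue)


def linear_annotation(prefix, scaffold, n, spacing=1000):
    return AnnotationSet(
        [
            make_gene(f"{prefix}{i}", scaffold, [(i * spacing, i * spacing + 500)])
            for i in range(n)
        ]
    )


class TestHighCopyFilter:
    def test_table_unchanged_below_cutoff(self):
        table = HitTable(tuple(hit(f"q{i}", f"s{i}") for i in range(10)))
        assert ms.filter_high_copy_hits(table, max_hits=50).hits == table.hits

    def test_over_cutoff_query_removed_entirely(self):
        over = [hit("hub", f"s{i}") for i in range(51)]
        keep = [hit("q1", "s_a"), hit("q2", "s_b")]
        filtered = ms.filter_high_copy_hits(HitTable(tuple(over + keep)), max_hits=50)
        assert filtered.queries() == {"q1", "q2"}

    def test_cascade_reaches_fixed_point(self):
        # removing q1 and s3 (both over the cutoff of 2) leaves only q3->s4
        hits = [
            hit("q1", "s1"), hit("q1", "s2"), hit("q1", "s3"),
            hit("q2", "s3"), hit("q3", "s3"), hit("q3", "s4"),
        ]
        filtered = ms.filter_high_copy_hits(HitTable(tuple(hits)), max_hits=2)
        assert [(h.query, h.subject) for h in filtered] == [("q3", "s4")]

    def test_fixed_point_property(self, rng):
        hits = tuple(
            hit(f"q{int(rng.integers(8))}", f"s{int(rng.integers(8))}x")
            for _ in range(200)
        )
        filtered = ms.filter_high_copy_hits(HitTable(hits), max_hits=10)
        from collections import Counter

        qc = Counter(h.query for h in filtered)
        sc = Counter(h.subject for h in filtered)
        assert all(c <= 10 for c in qc.values())
        assert all(c <= 10 for c in sc.values())
        assert set(filtered.hits) <= set(hits)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            ms.filter_high_copy_hits(HitTable(()), max_hits=0)


class TestGeneOrder:
    def test_ordinals_follow_span_start(self):
        ann = AnnotationSet(
            [
                make_gene("late", "c", [(20, 30)]),
                make_gene("first", "c", [(5, 8)]),
                make_gene("mid", "c", [(10, 15)]),
            ]
        )
        order = ms.build_gene_order(ann)
        assert order.orders["c"] == ("first", "mid", "late")
        assert order.index["late"] == ("c", 2)

    def test_scaffolds_have_independent_ordinals(self):
        ann = AnnotationSet(
            [make_gene("a", "c1", [(0, 10)]), make_gene("b", "c2", [(0, 10)])]
        )
        order = ms.build_gene_order(ann)
        assert order.index["a"][1] == 0 and order.index["b"][1] == 0

    def test_equal_starts_tie_by_id(self):
        ann = AnnotationSet(
            [make_gene("zeta", "c", [(0, 10)]), make_gene("alpha", "c", [(0, 20)])]
        )
        assert ms.build_gene_order(ann).orders["c"] == ("alpha", "zeta")


class TestBestHit:
    def test_max_bitscore_wins(self):
        table = HitTable((hit("q", "s1", 200.0), hit("q", "s2", 150.0)))
        assert ms.best_hit_per_query(table).hits[0].subject == "s1"

    def test_bitscore_tie_broken_by_evalue_then_subject(self):
        table = HitTable(
            (hit("q", "sB", 200.0, 1e-50), hit("q", "sA", 200.0, 1e-60))
        )
        assert ms.best_hit_per_query(table).hits[0].subject == "sA"
        table2 = HitTable(
            (hit("q", "sB", 200.0, 1e-50), hit("q", "sA", 200.0, 1e-50))
        )
        assert ms.best_hit_per_query(table2).hits[0].subject == "sA"

    def test_recovers_planted_ortholog_map_with_decoys(self):
        spec = OrthoPairSimSpec(
            seed=8, n_genes=80, paralog_hit_rate=0.5, spurious_hit_rate=0.3
        )
        _, _, hits, truth = simulate_ortholog_pair(spec)
        best = ms.best_hit_per_query(hits)
        assert {(h.query, h.subject) for h in best} == set(truth.anchor_pairs)


class TestBlockDetection:
    def _identity_setup(self, n=10):
        ann_a = linear_annotation("a", "A", n)
        ann_b = linear_annotation("b", "B", n)
        anchors = HitTable(tuple(hit(f"a{i}", f"b{i}") for i in range(n)))
        return anchors, ms.build_gene_order(ann_a), ms.build_gene_order(ann_b)

    def test_identity_permutation_single_plus_block(self):
        anchors, oa, ob = self._identity_setup()
        blocks = ms.detect_synteny_blocks(anchors, oa, ob)
        assert len(blocks) == 1
        assert blocks[0].size == 10 and blocks[0].orientation == "+"

    def test_internal_inversion_hand_enumerated(self):
        # B order: 1 2 3 | 6 5 4 | 7 8 9 10 (1-based labels), max_gap 0
        ann_a = linear_annotation("a", "A", 10)
        b_sequence = [0, 1, 2, 5, 4, 3, 6, 7, 8, 9]
        ann_b = AnnotationSet(
            [
                make_gene(f"b{g}", "B", [(j * 1000, j * 1000 + 500)])
                for j, g in enumerate(b_sequence)
            ]
        )
        anchors = HitTable(tuple(hit(f"a{i}", f"b{i}") for i in range(10)))
        blocks = ms.detect_synteny_blocks(
            anchors, ms.build_gene_order(ann_a), ms.build_gene_order(ann_b),
            min_block=3, max_gap=0,
        )
        got = [([a for a, _ in blk.anchors], blk.orientation) for blk in blocks]
        assert got == [
            (["a0", "a1", "a2"], "+"),
            (["a3", "a4", "a5"], "-"),
            (["a6", "a7", "a8", "a9"], "+"),
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_permutation_matches_run_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        sigma = rng.permutation(n)  # B position j holds ortholog sigma[j]
        ann_a = linear_annotation("a", "A", n)
        ann_b = AnnotationSet(
            [
                make_gene(f"b{sigma[j]}", "B", [(j * 1000, j * 1000 + 500)])
                for j in range(n)
            ]
        )
        anchors = HitTable(tuple(hit(f"a{i}", f"b{i}") for i in range(n)))
        blocks = ms.detect_synteny_blocks(
            anchors, ms.build_gene_order(ann_a), ms.build_gene_order(ann_b),
            min_block=3, max_gap=0,
        )
        pos_of = np.empty(n, dtype=int)
        pos_of[sigma] = np.arange(n)  # B ordinal of ortholog i
        expected = collinear_runs(list(pos_of), min_block=3)
        assert len(blocks) == len(expected)
        got_sets = {frozenset(a for a, _ in blk.anchors) for blk in blocks}
        exp_sets = {frozenset(f"a{i}" for i in run) for run, _ in expected}
        assert got_sets == exp_sets

    def test_role_swap_symmetry(self):
        spec = OrthoPairSimSpec(seed=12, n_genes=90, inversions=((10, 9), (40, 12)))
        ann_a, ann_b, hits, _ = simulate_ortholog_pair(spec)
        oa, ob = ms.build_gene_order(ann_a), ms.build_gene_order(ann_b)
        anchors = ms.best_hit_per_query(hits)
        swapped = HitTable(
            tuple(
                Hit(h.subject, h.query, h.percent_identity, h.bitscore, h.evalue)
                for h in anchors
            )
        )
        fwd = ms.detect_synteny_blocks(anchors, oa, ob)
        rev = ms.detect_synteny_blocks(swapped, ob, oa)
        fwd_pairs = {frozenset(blk.anchors) for blk in fwd}
        rev_pairs = {frozenset((b, a) for a, b in blk.anchors) for blk in rev}
        assert fwd_pairs == rev_pairs

    def test_reversing_subject_scaffold_flips_orientation(self):
        anchors, oa, _ = self._identity_setup()
        reversed_b = AnnotationSet(
            [
                make_gene(f"b{9 - j}", "B", [(j * 1000, j * 1000 + 500)])
                for j in range(10)
            ]
        )
        blocks = ms.detect_synteny_blocks(anchors, oa, ms.build_gene_order(reversed_b))
        assert len(blocks) == 1 and blocks[0].orientation == "-"

    def test_anchors_unique_to_one_block(self):
        spec = OrthoPairSimSpec(seed=4, n_genes=120, inversions=((20, 10),))
        ann_a, ann_b, hits, _ = simulate_ortholog_pair(spec)
        anchors = ms.best_hit_per_query(hits)
        blocks = ms.detect_synteny_blocks(
            anchors, ms.build_gene_order(ann_a), ms.build_gene_order(ann_b)
        )
        seen = []
        for blk in blocks:
            seen.extend(blk.anchors)
        assert len(seen) == len(set(seen))
        assert set(seen) <= {(h.query, h.subject) for h in anchors}

    def test_planted_structure_recovered_with_noise(self):
        spec = OrthoPairSimSpec(
            seed=31, n_genes=150, inversions=((10, 12), (60, 10)),
            insertion_rate=0.05, paralog_hit_rate=0.2, spurious_hit_rate=0.1,
        )
        ann_a, ann_b, hits, truth = simulate_ortholog_pair(spec)
        anchors = ms.best_hit_per_query(hits)
        blocks = ms.detect_synteny_blocks(
            anchors, ms.build_gene_order(ann_a), ms.build_gene_order(ann_b)
        )
        recovered = {p for blk in blocks for p in blk.anchors}
        assert len(recovered & set(truth.anchor_pairs)) >= 0.95 * len(truth.anchor_pairs)
        # orientation flags of the long planted inversions are recovered exactly
        minus_anchors = {
            p for blk in blocks if blk.orientation == "-" for p in blk.anchors
        }
        for start, length in spec.inversions:
            planted = {truth.anchor_pairs[i] for i in range(start, start + length)}
            assert planted <= minus_anchors

    def test_duplicate_query_rejected(self):
        anchors, oa, ob = self._identity_setup(5)
        doubled = HitTable(anchors.hits + (hit("a0", "b3"),))
        with pytest.raises(ValueError, match="best_hit_per_query"):
            ms.detect_synteny_blocks(doubled, oa, ob)


class TestFisherPairTests:
    def _run(self, hit_pairs):
        queries = sorted({q for q, _ in hit_pairs})
        subjects = sorted({s for _, s in hit_pairs})
        ann_a = AnnotationSet(
            [make_gene(q, q.split(".")[0], [(i * 10, i * 10 + 5)])
             for i, q in enumerate(queries)]
        )
        ann_b = AnnotationSet(
            [make_gene(s, s.split(".")[0], [(i * 10, i * 10 + 5)])
             for i, s in enumerate(subjects)]
        )
        table = HitTable(tuple(hit(q, s) for q, s in hit_pairs))
        return ms.scaffold_pair_significance(
            table, ms.build_gene_order(ann_a), ms.build_gene_order(ann_b)
        )

    def test_closed_form_2_0_0_2(self):
        # two hits A1<->B1, two hits A2<->B2: table (2,0,0,2) for pair (A1,B1)
        results = self._run(
            [("A1.q1", "B1.s1"), ("A1.q2", "B1.s2"), ("A2.q1", "B2.s1"), ("A2.q2", "B2.s2")]
        )
        r = next(t for t in results if (t.scaffold_a, t.scaffold_b) == ("A1", "B1"))
        assert (r.a, r.b, r.c, r.d) == (2, 0, 0, 2)
        assert r.p == pytest.approx(1 / 6, abs=1e-12)

    def test_margins_sum_to_total_and_padj_bounds(self):
        results = self._run(
            [("A1.q1", "B1.s1"), ("A1.q2", "B2.s1"), ("A2.q1", "B1.s2"),
             ("A2.q2", "B2.s2"), ("A2.q3", "B2.s3")]
        )
        total = 5
        for r in results:
            assert r.a + r.b + r.c + r.d == total
            assert 0 < r.p <= 1
            assert r.p <= r.p_adj <= 1

    def test_zero_overlap_pair_p_is_one(self):
        results = self._run([("A1.q1", "B1.s1"), ("A2.q1", "B1.s2")])
        # pair (A1,B1): a=1 of col 2 -> not 1.0; construct a=0 case directly
        p = hypergeom_p_greater(0, 3, 3, 4)
        assert p == pytest.approx(1.0)
        from scipy.stats import fisher_exact

        assert fisher_exact([[0, 3], [3, 4]], alternative="greater")[1] == pytest.approx(1.0)
        assert results  # the pipeline path above produced output

    @pytest.mark.parametrize("seed", range(4))
    def test_agreement_with_enumeration_oracle(self, seed):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(seed)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p == pytest.approx(hypergeom_p_greater(a, b, c, d), abs=1e-12)

    def test_tail_monotone_in_a_with_fixed_margins(self):
        # fixed margins: row1 = 10, col1 = 10, N = 40
        previous = 1.1
        for a in range(0, 11):
            b = 10 - a
            c = 10 - a
            d = 40 - a - b - c
            p = hypergeom_p_greater(a, b, c, d)
            assert p <= previous + 1e-15
            previous = p


class TestDotplotAndClassification:
    def test_dotplot_export(self, tmp_path):
        ann_a = linear_annotation("a", "A", 5)
        ann_b = linear_annotation("b", "B", 5)
        oa, ob = ms.build_gene_order(ann_a), ms.build_gene_order(ann_b)
        empty = ms.export_dotplot(HitTable(()), oa, ob, tmp_path / "empty.tsv")
        assert empty.read_text().splitlines() == [
            "scaffold_a\tordinal_a\tscaffold_b\tordinal_b\tbitscore"
        ]
        table = HitTable(tuple(hit(f"a{i}", f"b{i}") for i in range(5)))
        out = ms.export_dotplot(table, oa, ob, tmp_path / "diag.tsv")
        rows = [l.split("\t") for l in out.read_text().splitlines()[1:]]
        assert all(r[1] == r[3] for r in rows)  # identity map -> main diagonal

    def test_dotplot_shows_planted_inversion(self, tmp_path):
        spec = OrthoPairSimSpec(seed=2, n_genes=60, inversions=((10, 10),))
        ann_a, ann_b, hits, truth = simulate_ortholog_pair(spec)
        out = ms.export_dotplot(
            ms.best_hit_per_query(hits),
            ms.build_gene_order(ann_a),
            ms.build_gene_order(ann_b),
            tmp_path / "inv.tsv",
        )
        rows = [l.split("\t") for l in out.read_text().splitlines()[1:]]
        coords = {r[0] + ":" + r[2]: [] for r in rows}
        for r in rows:
            coords[r[0] + ":" + r[2]].append((int(r[1]), int(r[3])))
        # at least one scaffold pair contains an anti-diagonal segment
        def has_antidiagonal(points):
            points = sorted(points)
            run = 1
            for (x1, y1), (x2, y2) in zip(points, points[1:]):
                if x2 - x1 == 1 and y2 - y1 == -1:
                    run += 1
                    if run >= 3:
                        return True
                else:
                    run = 1
            return False

        assert any(has_antidiagonal(pts) for pts in coords.values())

    def test_classify_syntenic_genes(self):
        ann = linear_annotation("a", "A", 10)
        assert set(ms.classify_syntenic_genes([], ann).values()) == {"non_syntenic"}
        block = ms.SyntenyBlock("A", "B", (("a0", "x"), ("a1", "y"), ("a2", "z")), "+")
        labels = ms.classify_syntenic_genes([block], ann)
        assert sum(v == "syntenic" for v in labels.values()) == 3
        assert sum(v == "non_syntenic" for v in labels.values()) == 7

    def test_classification_matches_generator_truth(self):
        spec = OrthoPairSimSpec(seed=9, n_genes=100, tandem_size=10, tandem_interleave=1)
        ann_a, ann_b, hits, truth = simulate_ortholog_pair(spec)
        anchors = ms.best_hit_per_query(hits)
        blocks = ms.detect_synteny_blocks(
            anchors, ms.build_gene_order(ann_a), ms.build_gene_order(ann_b)
        )
        labels = ms.classify_syntenic_genes(blocks, ann_a)
        # planted tandem-family genes have no orthologs: always non-syntenic
        assert all(labels[m] == "non_syntenic" for m in truth.tandem_members)


class TestTandemClusters:
    def _ann(self, n=12):
        return linear_annotation("g", "c", n)

    def test_adjacent_members(self):
        fam = {"g0": "f", "g1": "f", "g2": "f"}
        clusters = ms.detect_tandem_clusters(self._ann(), fam)
        assert len(clusters) == 1
        assert clusters[0].members == ("g0", "g1", "g2")
        assert clusters[0].interleaved_count == 0

    def test_interleaved_members(self):
        fam = {"g0": "f", "g2": "f", "g4": "f"}
        clusters = ms.detect_tandem_clusters(self._ann(), fam, max_interleave=1)
        assert len(clusters) == 1
        assert clusters[0].interleaved_count == 2

    def test_gap_too_large_no_cluster(self):
        fam = {"g0": "f", "g10": "f"}
        assert ms.detect_tandem_clusters(self._ann(), fam, max_interleave=3) == []

    def test_generator_tandem_array_recovered(self):
        spec = OrthoPairSimSpec(seed=6, n_genes=100, tandem_size=12, tandem_interleave=2)
        ann_a, _, _, truth = simulate_ortholog_pair(spec)
        clusters = ms.detect_tandem_clusters(
            ann_a, truth.family_map, min_cluster=3, max_interleave=3
        )
        assert len(clusters) == 1
        assert set(clusters[0].members) == set(truth.tandem_members)
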