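"""Exact association tests, ranking, criterion counting, segment clustering."""

import math
from fractions import Fraction
from itertools import combinations_with_replacement

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from autozygmap.association import (
    Segment,
    cluster_segments,
    genotypic_exact_test,
    rank_counts,
    recessive_exact_test,
    scan,
    top_k_segment_count,
    zero_hom_control_criterion,
)
from autozygmap.genotypes import GenotypeCounts, Marker, ValidationError
from autozygmap.haplotypes import case_homozygosity_mask
from autozygmap.tables import table_fixtures

from conftest import make_matrix


def counts(aff, unaff, chrom="1", pos=100):
    m = Marker(f"{chrom}:{pos}", chrom, pos, "A", "G")
    aff = tuple(aff) + (0,) * (3 - len(aff))
    unaff = tuple(unaff) + (0,) * (3 - len(unaff))
    return GenotypeCounts(m, aff, unaff)


def exact_oracle(row1, row2):
    """Independent probability-mass oracle in exact rational arithmetic."""
    cols = [a + b for a, b in zip(row1, row2)]
    n, r1 = sum(cols), sum(row1)
    if n == 0 or r1 == 0 or sum(row2) == 0:
        return Fraction(1)
    denom = math.comb(n, r1)

    def tables(j, remaining):
        if j == len(cols) - 1:
            if remaining <= cols[j]:
                yield (remaining,)
            return
        for a in range(min(cols[j], remaining) + 1):
            for rest in tables(j + 1, remaining - a):
                yield (a,) + rest

    def prob(t):
        return Fraction(math.prod(math.comb(c, a) for c, a in zip(cols, t)), denom)

    p_obs = prob(tuple(row1))
    return sum(p for t in tables(0, r1) if (p := prob(t)) <= p_obs)


C27_9 = math.comb(27, 9)


class TestRecessive:
    def test_fully_separated_table_is_one_over_choose(self):
        p = recessive_exact_test(counts((9, 0), (0, 18)))
        assert p == pytest.approx(1 / C27_9, rel=1e-12)
        assert p == pytest.approx(2.134e-07, rel=5e-4)

    def test_degenerate_margin_gives_one(self):
        assert recessive_exact_test(counts((9, 0), (18, 0))) == 1.0
        assert recessive_exact_test(counts((0, 0), (5, 5))) == 1.0

    def test_hypergeometric_closed_form(self):
        # aff 9/0, unaff 4/14: only the observed table is as improbable
        p = recessive_exact_test(counts((9, 0), (4, 14)))
        assert p == pytest.approx(math.comb(13, 9) / C27_9, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            recessive_exact_test(counts((9, 0), (-1, 18)))

    def test_monotone_in_hom_controls(self):
        ps = [
            recessive_exact_test(counts((9, 0), (k, 18 - k))) for k in range(0, 10)
        ]
        assert all(a <= b * (1 + 1e-12) for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("k,expected", [(0, 2.134e-07), (1, 2.134e-06), (2, 1.174e-05), (3, 4.694e-05)])
    def test_published_strata(self, k, expected):
        p = recessive_exact_test(counts((9, 0), (k, 18 - k)))
        assert p == pytest.approx(expected, rel=5e-4)


class TestGenotypic:
    @pytest.mark.parametrize(
        "unaff,expected",
        [
            ((0, 8, 10), 2.134e-07),
            ((1, 6, 11), 2.134e-06),
            ((1, 7, 10), 4.267e-06),
            ((1, 8, 9), 6.401e-06),
            ((2, 4, 12), 1.174e-05),
            ((2, 10, 6), 1.387e-05),
            ((2, 8, 8), 1.984e-05),
            ((2, 7, 9), 3.136e-05),
            ((3, 10, 5), 9.388e-05),
        ],
    )
    def test_published_strata(self, unaff, expected):
        p = genotypic_exact_test(counts((9, 0, 0), unaff))
        assert p == pytest.approx(expected, rel=5e-4)

    def test_all_published_rows_reproduce(self):
        for row in table_fixtures():
            test = genotypic_exact_test if row.model == "genotypic" else recessive_exact_test
            assert test(row.counts) == pytest.approx(row.reported_p, rel=5e-4), (
                row.model,
                row.counts.marker.id,
            )


class TestOracleEquivalence:
    def test_full_2x2_sweep_small_totals(self):
        # every 2x2 margin configuration with total <= 30
        for n in range(1, 31):
            for r1 in range(0, n + 1):
                for c1 in range(0, n + 1):
                    a = min(r1, c1)  # one representative table per margin set
                    row1 = (a, r1 - a)
                    row2 = (c1 - a, n - r1 - (c1 - a))
                    if min(row2) < 0:
                        continue
                    p = recessive_exact_test(counts(row1, row2))
                    assert p == pytest.approx(
                        float(exact_oracle(row1, row2)), rel=1e-12, abs=1e-300
                    )

    def test_2x2_against_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 12, size=4)
            if t[:2].sum() == 0 or t[2:].sum() == 0:
                continue
            p = recessive_exact_test(counts(tuple(t[:2]), tuple(t[2:])))
            _, p_sp = fisher_exact(t.reshape(2, 2))
            assert p == pytest.approx(p_sp, rel=1e-9)

    @given(
        st.lists(st.integers(0, 10), min_size=3, max_size=3),
        st.lists(st.integers(0, 10), min_size=3, max_size=3),
    )
    def test_2x3_matches_rational_oracle(self, row1, row2):
        if sum(row1) + sum(row2) > 30:
            row1 = [min(r, 5) for r in row1]
            row2 = [min(r, 5) for r in row2]
        p = genotypic_exact_test(counts(tuple(row1), tuple(row2)))
        assert p == pytest.approx(float(exact_oracle(row1, row2)), rel=1e-12, abs=1e-300)

    def test_zero_margin_returns_one(self):
        assert genotypic_exact_test(counts((0, 0, 0), (3, 4, 5))) == 1.0
        assert recessive_exact_test(counts((3, 2), (0, 0))) == 1.0


class TestScan:
    def test_implanted_segment_passes_filter(self, default_cohort):
        gm = default_cohort.genotypes.copy()
        from autozygmap.genotypes import compute_allele_frequencies

        compute_allele_frequencies(gm)
        mask = case_homozygosity_mask(gm)
        idx = [gm.markers.index_of(mid) for mid in default_cohort.truth.interval_marker_ids]
        assert all(mask[i] for i in idx)

    def test_het_case_fails_filter(self):
        dosage = [[2], [1], [2]] + [[0]] * 6
        statuses = ["case"] * 3 + ["control"] * 6
        gm = make_matrix(dosage, statuses=statuses)
        results = scan(gm)
        assert not results[0].passes_case_hom_filter
        assert results[0].rank is None

    def test_no_cases_raises(self):
        gm = make_matrix([[0], [1]], statuses=["control", "control"])
        with pytest.raises(ValidationError, match="no cases"):
            scan(gm)

    def test_published_table_order_reproduced(self):
        # ranking the printed genotypic rows by our p reproduces the
        # printed (p-sorted) order of p values
        rows = table_fixtures("genotypic")
        ranked = rank_counts([r.counts for r in rows], "genotypic")
        assert all(r.rank is not None for r in ranked)
        recomputed_sorted = [r.p for r in ranked]
        assert recomputed_sorted == sorted(recomputed_sorted)
        # grouped identically to the published strata
        published = [row.reported_p for row in rows]
        for ours, printed in zip(recomputed_sorted, published):
            assert ours == pytest.approx(printed, rel=5e-4)


class TestCriteria:
    def test_zero_hom_control_on_published_recessive_rows(self):
        rows = table_fixtures("recessive")
        results = rank_counts([r.counts for r in rows], "recessive")
        subset = zero_hom_control_criterion(results)
        assert len(subset) == 9
        by_chrom = {}
        for r in subset:
            by_chrom[r.marker.chrom] = by_chrom.get(r.marker.chrom, 0) + 1
        assert by_chrom == {"9": 7, "34": 2}

    def test_hom_control_excluded(self):
        results = rank_counts([counts((9, 0, 0), (1, 5, 12)).__class__(
            counts((9, 0, 0), (1, 5, 12)).marker,
            (9, 0, 0), (1, 5, 12))], "genotypic")
        assert zero_hom_control_criterion(results) == []

    def test_empty_when_all_have_hom_controls(self):
        results = rank_counts(
            [counts((9, 0, 0), (2, 5, 11), pos=100 * (i + 1)) for i in range(3)],
            "genotypic",
        )
        assert zero_hom_control_criterion(results) == []

    def test_top25_published_genotypic_in_12mb_segment(self):
        rows = table_fixtures("genotypic")
        results = rank_counts([r.counts for r in rows], "genotypic")
        seg = Segment("9", 18_958_229, 30_966_212)
        assert top_k_segment_count(results, 25, seg) == 18

    def test_top_k_edge_cases(self):
        rows = table_fixtures("genotypic")
        results = rank_counts([r.counts for r in rows], "genotypic")
        seg = Segment("9", 1, 400_000_000)
        assert top_k_segment_count(results, 0, seg) == 0
        all_chr9 = sum(1 for r in results if r.marker.chrom == "9")
        assert top_k_segment_count(results, 10_000, seg) == all_chr9

    @pytest.mark.parametrize("seed", range(5))
    def test_top_k_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(40):
            unaff = tuple(int(x) for x in rng.multinomial(18, [0.2, 0.4, 0.4]))
            rows.append(
                counts((9, 0, 0), unaff, chrom=str(rng.integers(1, 4)), pos=int(rng.integers(1, 10**7)))
            )
        # dedupe positions per chromosome
        seen = set()
        rows = [r for r in rows if not ((r.marker.chrom, r.marker.pos) in seen or seen.add((r.marker.chrom, r.marker.pos)))]
        results = rank_counts(rows, "genotypic")
        seg = Segment("2", 10**6, 5 * 10**6)
        k = int(rng.integers(0, len(rows) + 5))
        expected = sum(
            1 for r in results
            if r.rank is not None and r.rank <= k and r.marker.chrom == seg.chrom
            and seg.start_pos <= r.marker.pos <= seg.end_pos
        )
        assert top_k_segment_count(results, k, seg) == expected


class TestSegments:
    def mk(self, chrom_pos):
        return [Marker(f"{c}:{p}", c, p, "A", "G") for c, p in chrom_pos]

    def test_single_marker(self):
        segs = cluster_segments(self.mk([("1", 500)]))
        assert segs == [Segment("1", 500, 500, 1)]

    def test_gap_rule_splits(self):
        segs = cluster_segments(self.mk([("1", 10**6), ("1", 7 * 10**6)]), max_gap_bp=5_000_000)
        assert len(segs) == 2
        segs = cluster_segments(self.mk([("1", 10**6), ("1", 5 * 10**6)]), max_gap_bp=5_000_000)
        assert len(segs) == 1
        assert segs[0].n_markers == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_partition(self, seed):
        rng = np.random.default_rng(100 + seed)
        markers = []
        for chrom in ("1", "2"):
            pos = np.sort(rng.choice(np.arange(1, 10**7), size=30, replace=False))
            markers += [Marker(f"{chrom}:{p}", chrom, int(p), "A", "G") for p in pos]
        gap = int(rng.integers(10**5, 3 * 10**6))
        segs = cluster_segments(markers, max_gap_bp=gap)
        # brute-force: walk and split
        expected = []
        cur = [markers[0]]
        for prev, m in zip(markers, markers[1:]):
            if m.chrom != prev.chrom or m.pos - prev.pos > gap:
                expected.append(cur)
                cur = []
            cur.append(m)
        expected.append(cur)
        assert len(segs) == len(expected)
        for s, grp in zip(segs, expected):
            assert (s.chrom, s.start_pos, s.end_pos, s.n_markers) == (
                grp[0].chrom, grp[0].pos, grp[-1].pos, len(grp)
            )

    def test_published_chr9_positions_cluster(self):
        # the printed top-50 chr9 rows leave a 5.66 Mb gap (19.3 -> 24.97 Mb)
        # that the full marker set would bridge: two blocks at the 5 Mb
        # default, one block once the gap rule admits it
        rows = [r for r in table_fixtures("genotypic") if r.counts.marker.chrom == "9"]
        markers = sorted((r.counts.marker for r in rows), key=lambda m: m.pos)
        segs = cluster_segments(markers, max_gap_bp=5_000_000)
        assert [s.n_markers for s in segs] == [6, 28]
        merged = cluster_segments(markers, max_gap_bp=6_000_000)
        assert len(merged) == 1
        assert merged[0].start_pos == 18_958_229
        assert merged[0].end_pos == 30_966_212
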