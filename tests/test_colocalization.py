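"""IntervalStats-style placement p-values and the asymmetric 1D matrix.

The independent oracle enumerates every placement of the query length
inside the domain and counts placements whose gap to the reference set
is no larger than the observed gap.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hidpet.colocalization import (
    SimilarityMatrix,
    build_1d_matrix,
    derive_directions,
    interval_distance,
    intervalstats_pvalue,
)
from hidpet.formats import GenomicInterval, IntervalSet

from conftest import make_intervals


def gap(qs, qe, rs, re):
    return max(0, rs - qe, qs - re)


def brute_force_pvalue(q, refs, domain):
    """Enumerate all placements of length |q| inside the domain segments."""
    length = q.end - q.start
    ref_list = [(r.start, r.end) for r in refs.on(q.chrom)]
    if not ref_list:
        return 1.0
    d_obs = min(gap(q.start, q.end, rs, re) for rs, re in ref_list)
    total = hits = 0
    for seg in domain.on(q.chrom):
        for s in range(seg.start, seg.end - length + 1):
            total += 1
            d = min(gap(s, s + length, rs, re) for rs, re in ref_list)
            if d <= d_obs:
                hits += 1
    return hits / total


class TestIntervalDistance:
    def test_gap(self):
        refs = make_intervals("r", [("chr1", 50, 60)])
        assert interval_distance(GenomicInterval("chr1", 70, 80), refs) == 10

    def test_containment_is_zero(self):
        refs = make_intervals("r", [("chr1", 50, 60)])
        assert interval_distance(GenomicInterval("chr1", 55, 58), refs) == 0

    def test_empty_chromosome_is_infinite(self):
        refs = make_intervals("r", [("chr2", 0, 10)])
        assert math.isinf(interval_distance(GenomicInterval("chr1", 0, 5), refs))


class TestPlacementPvalue:
    def test_worked_example(self):
        # domain [0,100), ref [50,60), q=[70,80): d=10, 41 of 91 placements
        domain = make_intervals("d", [("chr1", 0, 100)])
        refs = make_intervals("r", [("chr1", 50, 60)])
        q = GenomicInterval("chr1", 70, 80)
        p = intervalstats_pvalue(q, refs, domain)
        assert Fraction(p).limit_denominator(1000) == Fraction(41, 91)
        assert p == brute_force_pvalue(q, refs, domain)

    def test_ref_covering_domain_gives_one(self):
        domain = make_intervals("d", [("chr1", 0, 100)])
        refs = make_intervals("r", [("chr1", 0, 100)])
        for q in (GenomicInterval("chr1", 3, 9), GenomicInterval("chr1", 80, 95)):
            assert intervalstats_pvalue(q, refs, domain) == 1.0

    def test_on_target_overlap(self):
        domain = make_intervals("d", [("chr1", 0, 200)])
        refs = make_intervals("r", [("chr1", 100, 104)])
        q = GenomicInterval("chr1", 100, 110)
        p = intervalstats_pvalue(q, refs, domain)
        assert p == brute_force_pvalue(q, refs, domain)
        assert 0 < p < 0.1

    def test_no_refs_gives_one(self):
        domain = make_intervals("d", [("chr1", 0, 100)])
        refs = IntervalSet("r", [])
        assert intervalstats_pvalue(GenomicInterval("chr1", 0, 10), refs, domain) == 1.0

    def test_query_longer_than_domain_rejected(self):
        domain = make_intervals("d", [("chr1", 0, 20)])
        refs = make_intervals("r", [("chr1", 0, 5)])
        with pytest.raises(ValueError):
            intervalstats_pvalue(GenomicInterval("chr1", 0, 30), refs, domain)

    @settings(max_examples=120, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_enumeration(self, data):
        dom_len = data.draw(st.integers(50, 2000))
        qlen = data.draw(st.integers(1, 30))
        qstart = data.draw(st.integers(0, dom_len - qlen))
        n_refs = data.draw(st.integers(1, 5))
        refs = []
        for _ in range(n_refs):
            rlen = data.draw(st.integers(1, 40))
            rstart = data.draw(st.integers(0, dom_len - rlen))
            refs.append(("chr1", rstart, rstart + rlen))
        domain = make_intervals("d", [("chr1", 0, dom_len)])
        rset = make_intervals("r", refs)
        q = GenomicInterval("chr1", qstart, qstart + qlen)
        assert intervalstats_pvalue(q, rset, domain) == pytest.approx(
            brute_force_pvalue(q, rset, domain), abs=0
        )

    def test_monotone_in_distance(self):
        domain = make_intervals("d", [("chr1", 0, 5000)])
        refs = make_intervals("r", [("chr1", 2000, 2100)])
        ps = [
            intervalstats_pvalue(GenomicInterval("chr1", 2100 + d, 2150 + d), refs, domain)
            for d in (0, 10, 100, 400, 1000)
        ]
        assert ps == sorted(ps)


class TestMatrixAndDirections:
    def test_tiny_matrix_equals_per_peak_oracle(self):
        domain = make_intervals("d", [("chr1", 0, 10_000)])
        sets = [
            make_intervals("A", [("chr1", 100, 200), ("chr1", 5000, 5100)]),
            make_intervals("B", [("chr1", 120, 210), ("chr1", 9000, 9050)]),
            make_intervals("C", [("chr1", 4000, 4050)]),
        ]
        M = build_1d_matrix(sets, domain, alpha=0.05)
        for i, qs in enumerate(sets):
            for j, rs in enumerate(sets):
                if i == j:
                    continue
                expected = sum(
                    brute_force_pvalue(q, rs, domain) < 0.05 for q in qs
                ) / len(qs)
                assert M.values[i, j] == pytest.approx(expected, abs=0)

    def test_similarities_are_rational_in_peak_count(self):
        domain = make_intervals("d", [("chr1", 0, 10_000)])
        rng = np.random.default_rng(0)
        sets = []
        for name in ("A", "B"):
            starts = sorted(rng.integers(0, 9900, size=7))
            sets.append(make_intervals(name, [("chr1", int(s), int(s) + 50) for s in starts]))
        M = build_1d_matrix(sets, domain)
        for i, ps in enumerate(sets):
            for j in range(len(sets)):
                if i != j:
                    assert (M.values[i, j] * len(ps)) == pytest.approx(
                        round(M.values[i, j] * len(ps))
                    )

    def test_empty_peak_set_rejected_by_name(self):
        sets = [make_intervals("A", [("chr1", 0, 10)]), IntervalSet("B", [])]
        with pytest.raises(ValueError, match="B"):
            build_1d_matrix(sets)

    def test_directions(self):
        M = SimilarityMatrix(
            ["a", "b", "c"],
            np.array([[np.nan, 0.4, 0.3], [0.2, np.nan, 0.3], [0.3, 0.3, np.nan]]),
        )
        assert derive_directions(M) == [("a", "b")]  # c ties with both -> removed

    def test_all_symmetric_matrix_has_no_directions(self):
        v = np.full((3, 3), 0.2)
        np.fill_diagonal(v, np.nan)
        assert derive_directions(SimilarityMatrix(["a", "b", "c"], v)) == []

    def test_identical_peak_sets_fully_similar(self):
        domain = make_intervals("d", [("chr1", 0, 100_000)])
        peaks = [("chr1", s, s + 100) for s in range(10_000, 60_000, 10_000)]
        sets = [make_intervals("A", peaks), make_intervals("B", peaks)]
        M = build_1d_matrix(sets, domain)
        assert M.values[0, 1] == 1.0 and M.values[1, 0] == 1.0
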