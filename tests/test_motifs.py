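"""Exact PWM scanning, rank enrichment, TF lists, threshold optimization.

The scan oracle enumerates all 4^w k-mers, scores each with the same
discretized log-odds table, and sums background probabilities of
k-mers scoring at least as high.
"""

import itertools
import math

import numpy as np
import pytest

from hidpet.formats import BASES, GenomicInterval, IntervalSet, Loop, PWMRecord
from hidpet.loops import annotate_anchors
from hidpet.motifs import (
    DEFAULT_THRESHOLD_GRID,
    PWMScanner,
    ScanConfig,
    build_tf_lists,
    optimize_threshold,
    rank_enrichment,
    scan_pwm_exact,
)


def enumeration_pvalue(scanner: PWMScanner, int_score: int) -> float:
    """Oracle: exhaustive k-mer enumeration on the discretized score table."""
    w = scanner.pwm.width
    bg = scanner.cfg.background
    p = 0.0
    for kmer in itertools.product(range(4), repeat=w):
        s = int(scanner.int_scores[np.arange(w), list(kmer)].sum())
        if s >= int_score:
            p += math.prod(bg[b] for b in kmer)
    return p


def random_pwm(rng, width):
    m = rng.dirichlet(np.ones(4), size=width)
    return PWMRecord(f"m{width}", "TF", m)


class TestExactScan:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWMRecord("u", "TF", np.full((2, 4), 0.25))
        cfg = ScanConfig()
        scanner = PWMScanner(pwm, cfg)
        sites = scanner.site_scores("ACGTACGT")
        assert all(s == 0 for _, _, s in sites)
        assert scanner.pvalue_of_int(0) == pytest.approx(1.0)
        assert scan_pwm_exact("ACGTACGT", pwm, cfg) == []

    def test_count_pwm_on_acac_matches_enumeration(self):
        counts = np.array([[100.0, 0, 0, 0], [0, 100.0, 0, 0]])
        pwm = PWMRecord("ac", "TF", counts / counts.sum(axis=1, keepdims=True))
        cfg = ScanConfig(p_threshold=0.5)
        scanner = PWMScanner(pwm, cfg)
        for pos, strand, s in scanner.site_scores("ACAC"):
            assert scanner.pvalue_of_int(s) == pytest.approx(enumeration_pvalue(scanner, s))

    def test_dp_matches_enumeration_random_pwms(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            width = int(rng.integers(1, 6))
            scanner = PWMScanner(random_pwm(rng, width), ScanConfig())
            seq = "".join(BASES[i] for i in rng.integers(0, 4, size=12))
            for _, _, s in scanner.site_scores(seq):
                assert scanner.pvalue_of_int(s) == pytest.approx(
                    enumeration_pvalue(scanner, s), rel=1e-12
                )

    def test_default_threshold(self):
        assert ScanConfig().p_threshold == 1e-10

    def test_n_windows_skipped(self):
        pwm = PWMRecord("m", "TF", np.array([[0.97, 0.01, 0.01, 0.01]] * 2))
        scanner = PWMScanner(pwm, ScanConfig(p_threshold=0.9))
        positions = {pos for pos, _, _ in scanner.site_scores("AANAA")}
        assert positions == {0, 3}

    def test_lowering_threshold_never_adds_occurrences(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 5)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=60))
        prev = None
        for thr in (1e-1, 1e-2, 1e-3, 1e-4):
            hits = {
                (o.position, o.strand)
                for o in scan_pwm_exact(seq, pwm, ScanConfig(p_threshold=thr))
            }
            if prev is not None:
                assert hits <= prev
            prev = hits


class TestRankEnrichment:
    def hypergeom_oracle(self, ranked, positives):
        """Exhaustive hypergeometric over all cutoffs."""
        from math import comb

        order = sorted(ranked, key=lambda t: (-t[1], t[0]))
        N, K = len(order), len(positives)
        best = 1.0
        x = 0
        for k in range(1, N + 1):
            if order[k - 1][0] in positives:
                x += 1
            tail = sum(
                comb(K, i) * comb(N - K, k - i) for i in range(x, min(K, k) + 1)
            ) / comb(N, k)
            best = min(best, tail)
        return best

    def test_top_two_of_four(self):
        ranked = [("a", 4.0), ("b", 3.0), ("c", 2.0), ("d", 1.0)]
        p = rank_enrichment(ranked, {"a", "b"})
        assert p == pytest.approx(1 / 6)
        assert p == pytest.approx(self.hypergeom_oracle(ranked, {"a", "b"}))

    def test_all_positives_is_one(self):
        ranked = [("a", 4.0), ("b", 3.0), ("c", 2.0)]
        assert rank_enrichment(ranked, {"a", "b", "c"}) == pytest.approx(1.0)

    def test_bottom_ranked_is_one(self):
        ranked = [("a", 4.0), ("b", 3.0), ("c", 2.0), ("d", 1.0)]
        p = rank_enrichment(ranked, {"c", "d"})
        assert p == pytest.approx(self.hypergeom_oracle(ranked, {"c", "d"}))
        assert p == pytest.approx(1.0)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            ranked = [(f"x{i}", float(rng.normal())) for i in range(n)]
            k = int(rng.integers(1, n))
            positives = set(rng.choice([a for a, _ in ranked], size=k, replace=False))
            assert rank_enrichment(ranked, positives) == pytest.approx(
                self.hypergeom_oracle(ranked, positives)
            )

    def test_foreign_positives_rejected(self):
        with pytest.raises(ValueError):
            rank_enrichment([("a", 1.0)], {"zzz"})


def _toy_loop_world(tf_in_enh=("TF1",), tf_in_prom=("TF1",), n_loops=10, n_implanted=3):
    """``n_loops`` EP loops; chosen TF consensi implanted in the enhancer /
    promoter anchors of the first ``n_implanted`` loops, the rest unbound
    (so promoter rank enrichment has a real background to beat)."""
    cons = {"TF1": "ACGTACGTACGTACGTAC", "TF2": "GGGTTTAAACCCGGGTTT"}
    rng = np.random.default_rng(0)
    seq = list("".join(BASES[i] for i in rng.integers(0, 4, size=n_loops * 2000 + 1000)))
    raw_loops, states_iv = [], []
    for k in range(n_loops):
        base = 100 + k * 2000
        enh = GenomicInterval("chr1", base, base + 300)
        prom = GenomicInterval("chr1", base + 800, base + 1100)
        states_iv.append(GenomicInterval("chr1", enh.start, enh.end, label="Strong_Enhancer"))
        states_iv.append(GenomicInterval("chr1", prom.start, prom.end, label="Active_Promoter"))
        if k < n_implanted:
            for i, tf in enumerate(tf_in_enh):
                s = cons[tf]
                seq[enh.start + 10 + i * 25 : enh.start + 10 + i * 25 + len(s)] = list(s)
            for i, tf in enumerate(tf_in_prom):
                s = cons[tf]
                seq[prom.start + 10 + i * 25 : prom.start + 10 + i * 25 + len(s)] = list(s)
        raw_loops.append(Loop(enh, prom, 9))
    genome = {"chr1": "".join(seq)}
    loops = annotate_anchors(raw_loops, IntervalSet("s", states_iv))
    pwms = []
    for tf, s in cons.items():
        m = np.full((len(s), 4), 0.01)
        for j, base in enumerate(s):
            m[j, BASES.index(base)] = 0.97
        pwms.append(PWMRecord(f"M_{tf}", tf, m))
    return loops, genome, pwms


class TestTFLists:
    def test_tf_in_both_anchor_classes_in_final(self):
        loops, genome, pwms = _toy_loop_world(("TF1",), ("TF1",))
        lists = build_tf_lists(loops, genome, pwms)
        assert "TF1" in lists.final

    def test_enhancer_only_tf_not_in_final(self):
        loops, genome, pwms = _toy_loop_world(("TF2",), ())
        lists = build_tf_lists(loops, genome, pwms)
        assert "TF2" in lists.enhancer_tfs
        assert "TF2" not in lists.final

    def test_empty_pwm_collection_gives_empty_lists(self):
        loops, genome, _ = _toy_loop_world()
        lists = build_tf_lists(loops, genome, [])
        assert lists.enhancer_tfs == set() and lists.promoter_tfs == set()

    def test_final_is_intersection(self, landscape):
        from hidpet.loops import filter_ep_loops

        loops = filter_ep_loops(
            annotate_anchors(landscape.loops_by_cell["cellA"], landscape.states), "cellA"
        )
        lists = build_tf_lists(loops, landscape.genome, landscape.pwms)
        assert set(lists.final) == lists.enhancer_tfs & lists.promoter_tfs
        assert set(lists.final) <= lists.enhancer_tfs

    def test_no_loops_rejected(self):
        _, genome, pwms = _toy_loop_world()
        with pytest.raises(ValueError):
            build_tf_lists([], genome, pwms)


class TestOptimizeThreshold:
    def test_inflection_example(self):
        # oracle: finite differences by hand; largest |second difference| at index 2
        J = (0.9, 0.9, 0.9, 0.6, 0.3, 0.28, 0.27)
        second = [abs(J[i + 1] - 2 * J[i] + J[i - 1]) for i in range(1, 6)]
        assert int(np.argmax(second)) + 1 == 2
        per_cell = {
            "c1": dict(zip(DEFAULT_THRESHOLD_GRID, [set(range(int(100 * j))) for j in J])),
            "c2": dict(zip(DEFAULT_THRESHOLD_GRID, [set(range(100)) for _ in J])),
        }
        # simpler exact construction: X_i subset of Y with |X_i| = 100 J_i
        assert optimize_threshold(per_cell) == DEFAULT_THRESHOLD_GRID[2]

    def test_constant_curve_returns_default(self):
        per_cell = {
            "c1": {t: {"a", "b"} for t in DEFAULT_THRESHOLD_GRID},
            "c2": {t: {"a", "c"} for t in DEFAULT_THRESHOLD_GRID},
        }
        assert optimize_threshold(per_cell) == 1e-10

    def test_identical_sets_everywhere_returns_default(self):
        per_cell = {
            "c1": {t: {"a"} for t in DEFAULT_THRESHOLD_GRID},
            "c2": {t: {"a"} for t in DEFAULT_THRESHOLD_GRID},
        }
        assert optimize_threshold(per_cell) == 1e-10

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold({"c1": {}, "c2": {}}, grid=(1e-7, 1e-8))
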