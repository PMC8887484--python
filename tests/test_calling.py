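"""Counting, peak calling, the differential test, BH FDR, and merge rules."""
import numpy as np
import pytest
from scipy import stats as sps

from tripnseq import (
    DifferentialWindow,
    GenomeModel,
    GenomicInterval,
    ValidationError,
    bh_fdr,
    call_candidate_peaks,
    combine_and_merge,
    count_fragments,
    differential_window_test,
    tss_window_scan,
)
from tripnseq.calling import assign_genes, estimate_dispersion
from tripnseq.core import GeneAnnotation

from conftest import make_fragments


class TestCounting:
    def test_overlap_vs_midpoint_modes(self):
        frags = make_fragments([("chr1", 100, 400)])
        windows = [GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 200, 500)]
        assert list(count_fragments(frags, windows, "overlap")) == [1, 1]
        assert list(count_fragments(frags, windows, "midpoint")) == [0, 1]

    def test_empty_fragments_all_zero(self):
        frags = make_fragments([("chr2", 0, 10)])
        windows = [GenomicInterval("chr1", 0, 200)]
        assert list(count_fragments(frags, windows)) == [0]

    def test_matches_all_pairs_brute_force(self, rng):
        ivs = [
            ("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 9000, 2000), rng.integers(1, 600, 2000))
        ]
        frags = make_fragments(ivs)
        windows = [
            GenomicInterval("chr1", int(s), int(s) + 500)
            for s in rng.integers(0, 9000, 50)
        ]
        fast = count_fragments(frags, windows)
        for w, got in zip(windows, fast):
            brute = sum(1 for _, s, e in ivs if s < w.end and e > w.start)
            assert got == brute


class TestDifferentialTest:
    def test_exact_binomial_examples(self):
        # equal libraries, no overdispersion
        counts = np.array([[10, 10]])  # k=10 exp, 10 ctl -> t=20
        libs = np.array([1000, 1000])
        is_exp = np.array([True, False])
        _, p, _ = differential_window_test(counts, libs, is_exp, dispersion=0.0)
        assert p[0] == pytest.approx(float(sps.binom.sf(9, 20, 0.5)))
        assert p[0] == pytest.approx(0.5881, abs=1e-4)

        counts = np.array([[20, 0]])
        _, p, _ = differential_window_test(counts, libs, is_exp, dispersion=0.0)
        assert p[0] == pytest.approx(0.5**20)

    def test_zero_total_window_contract(self):
        counts = np.array([[0, 0]])
        lfc, p, _ = differential_window_test(
            counts, np.array([100, 100]), np.array([True, False]), dispersion=0.0
        )
        assert p[0] == 1.0 and lfc[0] == 0.0

    def test_betabinomial_reduces_to_binomial_at_zero_rho(self):
        counts = np.array([[30, 10]])
        libs = np.array([1000, 1000])
        is_exp = np.array([True, False])
        _, p0, _ = differential_window_test(counts, libs, is_exp, dispersion=0.0)
        _, p1, _ = differential_window_test(counts, libs, is_exp, dispersion=1e-12)
        assert p0[0] == pytest.approx(p1[0], rel=1e-9)

    def test_dispersion_recovery(self):
        """MoM estimate recovers the generating NB dispersion."""
        from tripnseq import simulate_null_window_counts

        counts, libs, is_exp = simulate_null_window_counts(
            n_windows=5000, dispersion=0.05, seed=42
        )
        est = estimate_dispersion(counts, libs, is_exp)
        assert est == pytest.approx(0.05, rel=0.25)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            differential_window_test(
                np.array([[1, 2]]), np.array([0, 10]), np.array([True, False])
            )
        with pytest.raises(ValidationError):
            differential_window_test(
                np.array([[1, 2]]), np.array([10, 10]), np.array([True, True])
            )


class TestBH:
    def test_hand_computed_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_fdr([1.0]), [1.0])

    def test_matches_brute_force_definition(self, rng):
        """q_(i) = min_{j>=i} m p_(j)/j on random vectors of varied length."""
        import statsmodels.stats.multitest as smm

        for _ in range(200):
            p = rng.random(int(rng.integers(1, 500)))
            q = bh_fdr(p)
            # independent oracle: statsmodels BH
            q_sm = smm.multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, q_sm, atol=1e-12)
            # sorted q non-decreasing
            assert np.all(np.diff(q[np.argsort(p, kind="stable")]) >= -1e-12)

    def test_brute_force_small(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 12)))
            m = len(p)
            srt = np.sort(p)
            brute_sorted = [
                min(min(m * srt[j] / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)
            ]
            assert np.allclose(np.sort(bh_fdr(p)), brute_sorted)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestPeakCalling:
    def _genome(self):
        return GenomeModel({"chr1": 1_000_000})

    def _uniform(self, rng, n, condition="BrdU+", sample="e1"):
        starts = rng.integers(0, 999_600, n)
        return make_fragments(
            [("chr1", int(s), int(s) + 300) for s in starts], sample, condition
        )

    def test_planted_peak_recovered(self):
        rng = np.random.Generator(np.random.PCG64(5))
        bg = self._uniform(rng, 20_000, "BrdU-", "c1")
        # experiment: uniform + 10x pileup over [500000, 501000)
        extra = [("chr1", int(s), int(s) + 300) for s in rng.integers(499_850, 500_850, 2000)]
        base = [("chr1", int(s), int(s) + 300) for s in rng.integers(0, 999_600, 20_000)]
        exp = make_fragments(base + extra, "e1", "BrdU+")
        peaks = call_candidate_peaks([exp], [bg], self._genome())
        hits = [p for p in peaks if p.start < 501_100 and p.end > 499_900]
        assert len(hits) == 1
        assert abs(hits[0].start - 499_900) <= 300
        assert abs(hits[0].end - 501_150) <= 300

    def test_null_yields_almost_no_peaks(self):
        rng = np.random.Generator(np.random.PCG64(6))
        frags = self._uniform(rng, 20_000)
        same = make_fragments(
            [("chr1", int(s), int(e)) for s, e in zip(frags.starts, frags.ends)],
            "c1",
            "BrdU-",
        )
        peaks = call_candidate_peaks([frags], [same], self._genome())
        assert len(peaks) <= 1  # Poisson false-positive allowance per 10 Mb

    def test_empty_input_rejected_and_background_fallback(self):
        rng = np.random.Generator(np.random.PCG64(7))
        with pytest.raises(ValidationError):
            call_candidate_peaks([], [], self._genome())
        frags = self._uniform(rng, 5000)
        peaks = call_candidate_peaks([frags], [], self._genome())
        assert isinstance(peaks, list)


class TestScanAndMerge:
    def test_offset_set_count(self):
        genome = GenomeModel({"chr1": 100_000})
        exp = make_fragments([("chr1", 50_000, 50_300)], "e1", "BrdU+")
        ctl = make_fragments([("chr1", 50_000, 50_300)], "c1", "BrdU-")
        windows = tss_window_scan(
            [("chr1", 50_000)], [exp, ctl], genome, dispersion=0.0
        )
        sets = {w.set_id for w in windows}
        assert len(sets) == 11  # (2*1000 - 1000)/100 + 1

    def test_combine_and_merge_examples(self):
        def dw(start, end, fdr, sid):
            return DifferentialWindow(
                GenomicInterval("chr1", start, end),
                np.array([1, 1]), 0.0, fdr, fdr, sid,
            )

        loci = combine_and_merge([dw(100, 600, 0.01, "a"), dw(500, 1500, 0.04, "b")])
        assert len(loci) == 1
        assert (loci[0].interval.start, loci[0].interval.end) == (100, 1500)
        assert loci[0].fdr == pytest.approx(0.04)  # highest member FDR kept

        loci = combine_and_merge([dw(0, 100, 0.01, "a"), dw(500, 600, 0.02, "a")])
        assert len(loci) == 2
        assert combine_and_merge([dw(0, 100, 0.06, "a")]) == []

    def test_merge_fixed_point_and_disjoint(self, rng):
        wins = [
            DifferentialWindow(
                GenomicInterval("chr1", int(s), int(s) + 400),
                np.array([1, 1]), 0.0, 0.01, float(f), "a",
            )
            for s, f in zip(rng.integers(0, 50_000, 100), rng.random(100) * 0.1)
        ]
        loci = combine_and_merge(wins)
        for a, b in zip(loci, loci[1:]):
            assert a.interval.end <= b.interval.start  # disjoint + sorted
        assert all(l.fdr <= 0.05 for l in loci)
        # re-running on its own output is a fixed point
        again = combine_and_merge(
            [
                DifferentialWindow(
                    l.interval, np.array([1, 1]), 0.0, l.fdr, l.fdr, "m"
                )
                for l in loci
            ]
        )
        assert [(l.interval.start, l.interval.end, l.fdr) for l in again] == [
            (l.interval.start, l.interval.end, l.fdr) for l in loci
        ]


class TestAssignGenes:
    def test_flank_rule(self):
        genes = [
            GeneAnnotation("a", "chr1", 9_000, 12_000, "+"),  # TSS 9000
            GeneAnnotation("b", "chr1", 8_000, 10_801, "-"),  # TSS 10800
            GeneAnnotation("c", "chr1", 11_600, 14_000, "+"),  # TSS 11600
        ]
        locus = combine_and_merge(
            [
                DifferentialWindow(
                    GenomicInterval("chr1", 9_500, 10_500),
                    np.array([1, 1]), 0.0, 0.01, 0.01, "a",
                )
            ]
        )
        loci, ctss = assign_genes(locus, genes, flank=1500)
        assert loci[0].genes == ["a", "b"]  # both within 1.5 kb of center 10 000
        assert [g.gene_id for g in ctss] == ["c"]
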