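"""Metagene matrices, median +- SE aggregation, scaled bodies, group tests."""
import numpy as np
import pytest

from tripnseq import (
    CoverageTrack,
    GenomeModel,
    GenomicInterval,
    ValidationError,
    aggregate,
    build_matrix,
    compare_region_groups,
    match_sample,
    scaled_body_matrix,
)
from tripnseq.core import GeneAnnotation


@pytest.fixture
def flat_genome():
    return GenomeModel({"c": 100_000})


def const_track(genome, value, bin_size=10):
    return CoverageTrack(
        bin_size,
        {c: np.full(-(-n // bin_size), float(value)) for c, n in genome.chrom_lengths.items()},
    )


class TestBuildMatrix:
    def test_constant_track(self, flat_genome):
        mat = build_matrix(
            [GenomicInterval("c", 5000, 5001)], const_track(flat_genome, 2.5),
            flat_genome, 500, 500, 10, anchor="start",
        )
        assert mat.values.shape == (1, 100)
        assert np.allclose(mat.values, 2.5)
        assert mat.offsets[0] == -500

    def test_strand_flip_reverses_minus_rows(self, flat_genome):
        track = const_track(flat_genome, 0.0)
        track.data["c"][:] = np.arange(len(track.data["c"]))
        plus = GenomicInterval("c", 5000, 5001, "+")
        minus = GenomicInterval("c", 5000, 5001, "-")
        m = build_matrix([plus, minus], track, flat_genome, 500, 500, 10,
                         anchor="start", strand_flip=True)
        assert np.allclose(m.values[1], m.values[0][::-1])
        # flip twice = identity
        again = build_matrix([minus], track, flat_genome, 500, 500, 10,
                             anchor="start", strand_flip=True)
        assert np.allclose(again.values[0][::-1], m.values[0])

    def test_blacklisted_region_excluded(self):
        genome = GenomeModel(
            {"c": 100_000}, blacklist=[GenomicInterval("c", 4900, 5100)]
        )
        mat = build_matrix(
            [GenomicInterval("c", 5000, 5001), GenomicInterval("c", 50_000, 50_001)],
            const_track(genome, 1.0), genome, 500, 500, 10, anchor="start",
        )
        assert mat.values.shape[0] == 1

    def test_edge_region_excluded(self, flat_genome):
        mat = build_matrix(
            [GenomicInterval("c", 100, 101)], const_track(flat_genome, 1.0),
            flat_genome, 500, 500, 10, anchor="start",
        )
        assert mat.values.shape[0] == 0


class TestAggregate:
    def test_median_and_se(self, flat_genome):
        from tripnseq.profiles import ProfileMatrix

        vals = np.array([[1.0], [2.0], [3.0]])
        mat = ProfileMatrix(["a", "b", "c"], np.array([0]), vals, 10, "point")
        agg = aggregate(mat)
        assert agg["median"][0] == pytest.approx(2.0)
        assert agg["se"][0] == pytest.approx(np.std([1, 2, 3]) / np.sqrt(3))
        assert agg["n"][0] == 3

    def test_single_row_and_permutation_invariance(self, rng):
        from tripnseq.profiles import ProfileMatrix

        vals = rng.random((10, 5))
        mat = ProfileMatrix([str(i) for i in range(10)], np.arange(5), vals, 1, "point")
        agg = aggregate(mat)
        perm = ProfileMatrix(
            [str(i) for i in range(10)], np.arange(5),
            vals[rng.permutation(10)], 1, "point",
        )
        agg_p = aggregate(perm)
        assert np.allclose(agg["median"], agg_p["median"])
        assert np.allclose(agg["se"], agg_p["se"])
        single = ProfileMatrix(["x"], np.arange(5), vals[:1], 1, "point")
        assert np.allclose(aggregate(single)["se"], 0.0)

    def test_missing_rows_excluded_from_n(self):
        from tripnseq.profiles import ProfileMatrix

        vals = np.array([[1.0], [np.nan], [3.0]])
        agg = aggregate(ProfileMatrix(["a", "b", "c"], np.array([0]), vals, 1, "point"))
        assert agg["n"][0] == 2
        assert agg["median"][0] == pytest.approx(2.0)


class TestScaledBody:
    def test_scaling_invariance_for_linear_track(self):
        """A track linear in gene-fractional position yields the same body
        profile for genes of different lengths."""
        genome = GenomeModel({"c": 1_000_000})
        bin_size = 100
        n = 1_000_000 // bin_size
        track = CoverageTrack(bin_size, {"c": np.zeros(n)})
        g_short = GeneAnnotation("s", "c", 100_000, 110_000, "+")
        g_long = GeneAnnotation("l", "c", 500_000, 600_000, "+")
        arr = track.data["c"]
        for g in (g_short, g_long):
            b0, b1 = g.start // bin_size, g.end // bin_size
            arr[b0:b1] = np.linspace(0, 1, b1 - b0)
        mat = scaled_body_matrix([g_short, g_long], track, genome,
                                 body_bins=50, flank=10_000, bin_size=100)
        body = mat.values[:, 100:150]
        assert np.allclose(body[0], body[1], atol=0.02)
        # flanks are unaffected by gene length (zero track outside bodies)
        assert np.allclose(mat.values[:, :100], 0.0)

    def test_constant_track_flat_profile(self):
        genome = GenomeModel({"c": 1_000_000})
        track = const_track(genome, 1.5, 100)
        g = GeneAnnotation("g", "c", 100_000, 150_000, "+")
        mat = scaled_body_matrix([g], track, genome, body_bins=20, flank=1000, bin_size=100)
        assert np.allclose(mat.values, 1.5)

    def test_too_short_gene_excluded(self):
        genome = GenomeModel({"c": 1_000_000})
        g = GeneAnnotation("g", "c", 100_000, 100_010, "+")
        mat = scaled_body_matrix([g], const_track(genome, 1, 100), genome,
                                 body_bins=100, flank=1000, bin_size=100)
        assert mat.values.shape[0] == 0


class TestMatchSample:
    def test_sampling_contracts(self, rng):
        regions = [GenomicInterval("c", i * 10, i * 10 + 5) for i in range(100)]
        sample = match_sample(regions, 20, seed=3)
        assert len(sample) == 20
        assert set(id(r) for r in sample) <= set(id(r) for r in regions)
        assert match_sample(regions, 20, seed=3) == sample  # deterministic
        assert match_sample(regions, 20, seed=4) != sample
        full = match_sample(regions, 100, seed=1)
        assert sorted(full, key=lambda r: r.start) == regions
        with pytest.raises(ValidationError):
            match_sample(regions, 101)


class TestCompareGroups:
    def test_identical_groups_p_one(self, flat_genome):
        track = const_track(flat_genome, 1.0)
        track.data["c"] += np.arange(len(track.data["c"])) * 0.01
        regions = [GenomicInterval("c", i * 1000, i * 1000 + 500) for i in range(5)]
        out = compare_region_groups(regions, regions, track, sub_window=100)
        assert out["p_value"] == 1.0

    def test_constant_offset_detected(self, flat_genome):
        rng = np.random.Generator(np.random.PCG64(8))
        base = rng.random(10_000)
        track_a = CoverageTrack(10, {"c": base + 1.0})
        track = CoverageTrack(10, {"c": base})
        ga = [GenomicInterval("c", i * 1000, i * 1000 + 500) for i in range(40)]
        a = compare_region_groups(ga, ga, track_a, sub_window=100)["summaries_a"]
        b = compare_region_groups(ga, ga, track, sub_window=100)["summaries_a"]
        assert np.allclose(a, b + 1.0)

    def test_planted_signal_detected(self, flat_genome):
        rng = np.random.Generator(np.random.PCG64(9))
        arr = rng.random(10_000)
        ga = [GenomicInterval("c", i * 1000, i * 1000 + 500) for i in range(50)]
        gb = [GenomicInterval("c", i * 1000 + 500, i * 1000 + 1000) for i in range(50)]
        for r in ga:
            arr[r.start // 10 : r.end // 10] *= 2.0
        track = CoverageTrack(10, {"c": arr})
        out = compare_region_groups(ga, gb, track, sub_window=100)
        assert out["p_value"] < 0.01
        assert out["median_a"] > out["median_b"]

    def test_label_permutation_null_is_uniform(self, flat_genome):
        """P-values under random group labels are ~uniform (KS distance)."""
        rng = np.random.Generator(np.random.PCG64(10))
        arr = rng.random(10_000)
        track = CoverageTrack(10, {"c": arr})
        regions = [GenomicInterval("c", i * 900, i * 900 + 400) for i in range(100)]
        ps = []
        for _ in range(200):
            idx = rng.permutation(100)
            a = [regions[i] for i in idx[:50]]
            b = [regions[i] for i in idx[50:]]
            ps.append(compare_region_groups(a, b, track, sub_window=100)["p_value"])
        from scipy import stats as sps

        d = sps.kstest(ps, "uniform").statistic
        assert d < 0.1

    def test_empty_group_rejected(self, flat_genome):
        with pytest.raises(ValidationError):
            compare_region_groups([], [GenomicInterval("c", 0, 10)],
                                  const_track(flat_genome, 1.0), 10)
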