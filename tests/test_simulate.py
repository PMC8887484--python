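"""Synthetic-data generator: determinism, planted-property recovery."""
import numpy as np
import pytest

from tripnseq import (
    SimulationConfig,
    ValidationError,
    compute_rfd,
    expected_rfd,
    gc_percent,
    generate_genome,
    simulate_null_window_counts,
    simulate_okseq,
    simulate_strand_transcription,
    simulate_tripn_fragments,
    simulate_variants,
)
from tripnseq.simulate import SyntheticTruth


SMALL = dict(
    n_chromosomes=2,
    chrom_length=600_000,
    n_tri=12,
    n_ctss=80,
    n_inactive=20,
    fragments_per_replicate=60_000,
)


@pytest.fixture(scope="module")
def small_bundle():
    cfg = SimulationConfig(seed=7, **SMALL)
    genome, genes, truth = generate_genome(cfg)
    return cfg, genome, genes, truth


class TestGenerateGenome:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        g1, genes1, t1 = generate_genome(cfg)
        g2, genes2, t2 = generate_genome(cfg)
        for c in g1.chroms:
            assert g1.sequence(c, 0, g1.chrom_lengths[c]) == g2.sequence(
                c, 0, g2.chrom_lengths[c]
            )
        assert [g.gene_id for g in genes1] == [g.gene_id for g in genes2]
        assert t1.orientation == t2.orientation

    def test_tri_promoters_more_gc_rich_than_background(self, small_bundle):
        cfg, genome, genes, truth = small_bundle
        def promoter_gc(g):
            lo, hi = g.tss - 400, g.tss + 400
            seq = genome.sequence(g.chrom, lo, hi)
            _, frac = gc_percent(seq, window=len(seq))
            return frac[0]

        tri_gc = np.mean([promoter_gc(g) for g in truth.genes_of_class("tri")])
        inact_gc = np.mean([promoter_gc(g) for g in truth.genes_of_class("inactive")])
        ctss_gc = np.mean([promoter_gc(g) for g in truth.genes_of_class("ctss")])
        assert tri_gc > ctss_gc > inact_gc

    def test_tri_downstream_gc_skew_positive(self, small_bundle):
        from tripnseq import gc_skew

        _, genome, _, truth = small_bundle
        skews = []
        for g in truth.genes_of_class("tri"):
            if g.strand == "+":
                seq = genome.sequence(g.chrom, g.tss, g.tss + 400)
            else:
                from tripnseq.metrics import revcomp

                seq = revcomp(genome.sequence(g.chrom, g.tss - 399, g.tss + 1))
            _, sk = gc_skew(seq, window=len(seq))
            skews.append(sk[0])
        assert np.mean(skews) > 0.2

    def test_gene_count_too_large_rejected(self):
        with pytest.raises(ValidationError):
            generate_genome(
                SimulationConfig(seed=1, n_chromosomes=1, chrom_length=100_000,
                                 n_tri=50, n_ctss=50, n_inactive=0)
            )

    def test_planted_loci_lie_in_tss_neighborhoods(self, small_bundle):
        _, _, _, truth = small_bundle
        by_id = {g.gene_id: g for g in truth.genes}
        for locus in truth.tri_loci:
            tss = by_id[locus.name].tss
            assert locus.start <= tss < locus.end


class TestFragments:
    def test_library_sizes_exact_and_deterministic(self, small_bundle):
        cfg, genome, genes, truth = small_bundle
        frags = simulate_tripn_fragments(cfg, truth, genome)
        assert len(frags) == 6
        assert all(f.library_size == cfg.fragments_per_replicate for f in frags)
        again = simulate_tripn_fragments(cfg, truth, genome)
        assert np.array_equal(frags[0].starts, again[0].starts)

    def test_fragment_lengths_in_configured_range(self, small_bundle):
        cfg, genome, genes, truth = small_bundle
        f = simulate_tripn_fragments(cfg, truth, genome)[0]
        lengths = f.ends - f.starts
        assert lengths.min() >= cfg.fragment_length[0]
        assert lengths.max() <= cfg.fragment_length[1]

    def test_planted_fold_recovered_in_expectation(self, small_bundle):
        """Background-corrected BrdU+/BrdU- ratio at TRIs ~ enrichment fold."""
        from tripnseq import count_fragments, GenomicInterval

        cfg, genome, genes, truth = small_bundle
        frags = simulate_tripn_fragments(cfg, truth, genome)
        windows = [
            GenomicInterval(l.chrom, l.start, l.end) for l in truth.tri_loci
        ]
        n_active = sum(1 for c in truth.gene_classes.values() if c != "inactive")
        mean_len = sum(cfg.fragment_length) / 2
        genome_bp = genome.total_length

        def corrected(cond):
            sets = [f for f in frags if f.condition == cond]
            counts = sum(count_fragments(f, windows) for f in sets)
            gene_mass = n_active * cfg.promoter_mean
            if cond == "BrdU+":
                gene_mass += cfg.n_tri * cfg.promoter_mean * (cfg.enrichment_fold - 1)
            bg_total = cfg.fragments_per_replicate - gene_mass
            # overlap counting widens each window by ~ one fragment length
            bg_per_window = bg_total * (2 * cfg.tri_flank + mean_len) / genome_bp
            return counts.mean() / len(sets) - bg_per_window

        ratio = corrected("BrdU+") / corrected("BrdU-")
        assert ratio == pytest.approx(cfg.enrichment_fold, rel=0.2)

    def test_null_fold_gives_similar_counts(self):
        from tripnseq import count_fragments, GenomicInterval
        from scipy import stats as sps

        cfg = SimulationConfig(seed=11, enrichment_fold=1.0, **SMALL)
        genome, genes, truth = generate_genome(cfg)
        frags = simulate_tripn_fragments(cfg, truth, genome)
        windows = [GenomicInterval(l.chrom, l.start, l.end) for l in truth.tri_loci]
        exp = sum(count_fragments(f, windows) for f in frags if f.condition == "BrdU+")
        ctl = sum(count_fragments(f, windows) for f in frags if f.condition == "BrdU-")
        _, p = sps.mannwhitneyu(exp, ctl)
        assert p > 0.01


class TestStrandTranscription:
    def test_orientation_constructions(self, small_bundle):
        cfg, genome, genes, truth = small_bundle
        plus_t, minus_t, plus_p, minus_p = simulate_strand_transcription(truth, genome)
        by_name = {}
        for p in plus_p + minus_p:
            by_name.setdefault(p.name, []).append(p)
        for g in truth.genes_of_class("tri"):
            orient = truth.orientation[g.gene_id]
            if orient == "divergent_pair":
                pid = truth.partners[g.gene_id]
                partner_peak = by_name[pid][0]
                # partner peak center within 3 kb upstream of the focal TSS
                assert abs(partner_peak.center - g.tss) < 3500
            elif orient == "single_bidirectional":
                assert g.gene_id + "_as" in by_name
        # inactive genes: zero signal on both strands
        for g in truth.genes_of_class("inactive"):
            for peaks in (plus_p, minus_p):
                assert not any(p.name.startswith(g.gene_id) for p in peaks)

    def test_classification_recovers_all_planted_labels(self, small_bundle):
        from tripnseq import classify_orientation

        cfg, genome, genes, truth = small_bundle
        _, _, plus_p, minus_p = simulate_strand_transcription(truth, genome)
        for g in truth.genes_of_class("tri"):
            call = classify_orientation(g, truth.genes, plus_p, minus_p)
            assert call.orientation == truth.orientation[g.gene_id], g.gene_id


class TestOkSeq:
    def _truth(self, origins):
        return SyntheticTruth([], [], {}, {}, {}, {"chr1": origins}, {})

    def test_single_efficient_origin_sign_pattern(self):
        from tripnseq import GenomeModel

        genome = GenomeModel({"chr1": 1_000_000})
        truth = self._truth([(500_000, 1.0)])
        sc = simulate_okseq(truth, genome, depth_per_mb=10_000, seed=2)
        rfd = compute_rfd(sc).data["chr1"]
        sign = np.sign(rfd[~np.isnan(rfd)])
        flips = np.flatnonzero(sign[1:] != sign[:-1])
        assert len(flips) == 1
        assert abs(int(flips[0]) + 1 - 500) <= 1  # within 1 bin of the origin

    def test_balanced_null_rfd_within_three_sigma(self):
        from tripnseq import GenomeModel

        genome = GenomeModel({"chr1": 1_000_000})
        truth = self._truth([])
        sc = simulate_okseq(truth, genome, depth_per_mb=20_000, seed=3)
        rfd = compute_rfd(sc).data["chr1"]
        n = sc.forward["chr1"] + sc.reverse["chr1"]
        ok = n > 0
        within = np.abs(rfd[ok]) < 3 / np.sqrt(n[ok])
        assert within.mean() >= 0.99

    def test_two_origins_termination_slope_matches_expectation(self):
        from tripnseq import GenomeModel

        genome = GenomeModel({"chr1": 1_000_000})
        origins = [(250_000, 1.0), (750_000, 1.0)]
        truth = self._truth(origins)
        sc = simulate_okseq(truth, genome, depth_per_mb=50_000, seed=4)
        rfd = compute_rfd(sc).data["chr1"]
        centers = np.arange(len(rfd)) * 1000 + 500
        exp = expected_rfd(origins, centers)
        ok = ~np.isnan(rfd)
        assert np.corrcoef(rfd[ok], exp[ok])[0, 1] > 0.95
        # hand-computed expectation: forks meet at the midpoint, so RFD is
        # +1 between the left origin and 500 kb, -1 after, +1 again after
        # the right origin
        assert exp[300] == pytest.approx(1.0)
        assert exp[600] == pytest.approx(-1.0)
        assert exp[800] == pytest.approx(1.0)

    def test_partial_efficiency_expected_rfd(self):
        # single origin with efficiency e, conditioned on firing -> |RFD| = 1
        exp = expected_rfd([(500, 0.5)], np.array([100.0, 900.0]))
        assert exp[0] == pytest.approx(-1.0)
        assert exp[1] == pytest.approx(1.0)

    def test_zero_depth_rejected(self):
        from tripnseq import GenomeModel

        with pytest.raises(ValidationError):
            simulate_okseq(self._truth([]), GenomeModel({"chr1": 1000}), 0)


class TestVariants:
    def test_deletion_rate_doubling_recovered(self):
        """Planted 2x deletion rate in TRI gene bodies, at a gene count where
        Poisson error on the density ratio is small."""
        cfg = SimulationConfig(
            seed=19, n_chromosomes=4, chrom_length=1_500_000,
            n_tri=100, n_ctss=300, n_inactive=50,
        )
        genome, genes, truth = generate_genome(cfg)
        records = simulate_variants(truth, genome, seed=5)
        from tripnseq.variants import VARIANT_CLASSES, _region_class_counts

        tri_iv = [g.interval() for g in truth.genes_of_class("tri")]
        ctl_iv = [g.interval() for g in truth.genes_of_class("ctss")]
        tri = _region_class_counts(records, tri_iv).sum(axis=0)
        ctl = _region_class_counts(records, ctl_iv).sum(axis=0)
        tri_bp = sum(len(iv) for iv in tri_iv)
        ctl_bp = sum(len(iv) for iv in ctl_iv)
        di = VARIANT_CLASSES.index("deletion")
        ratio = (tri[di] / tri_bp) / (ctl[di] / ctl_bp)
        assert ratio == pytest.approx(2.0, rel=0.3)
        # SBS rate is equal by construction
        si = VARIANT_CLASSES.index("SBS")
        sbs_ratio = (tri[si] / tri_bp) / (ctl[si] / ctl_bp)
        assert sbs_ratio == pytest.approx(1.0, rel=0.25)

    def test_zero_rates_give_empty_list(self, small_bundle):
        cfg, genome, genes, truth = small_bundle
        zero = {k: {c: 0.0 for c in v} for k, v in truth.variant_rates.items()}
        assert simulate_variants(truth, genome, rates=zero, seed=1) == []

    def test_vcf_round_trip(self, small_bundle, tmp_path):
        from tripnseq import read_vcf, write_vcf

        cfg, genome, genes, truth = small_bundle
        records = simulate_variants(truth, genome, seed=6)[:200]
        path = tmp_path / "v.vcf"
        write_vcf(records, str(path), contigs=genome.chrom_lengths)
        back = read_vcf(str(path))
        assert [(r.chrom, r.pos, r.ref, r.alt, r.vclass) for r in back] == [
            (r.chrom, r.pos, r.ref, r.alt, r.vclass) for r in sorted(
                set(records), key=lambda r: (r.chrom, r.pos, r.ref, r.alt)
            )
        ]

    def test_negative_rates_rejected(self, small_bundle):
        cfg, genome, genes, truth = small_bundle
        bad = {"sbs": {"tri_gene": -1.0, "control_gene": 0, "intergenic": 0}}
        with pytest.raises(ValidationError):
            simulate_variants(truth, genome, rates=bad)


class TestNullCounts:
    def test_shapes_and_determinism(self):
        c1, l1, e1 = simulate_null_window_counts(n_windows=100, seed=9)
        c2, _, _ = simulate_null_window_counts(n_windows=100, seed=9)
        assert c1.shape == (100, 6)
        assert np.array_equal(c1, c2)
        assert e1.sum() == 3
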