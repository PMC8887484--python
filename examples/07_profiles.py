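"""Metagene profiles and region-group comparison.

Builds a TSS-anchored signal matrix from the simulated nascent-transcription
track, aggregates it as per-bin median +- SE, and compares TRI vs size-
matched control TSS windows with the region-summary rank-sum procedure
(median per sub-window, mean across the region).
"""
import numpy as np

import tripnseq as t

cfg = t.SimulationConfig(
    seed=9, n_chromosomes=2, chrom_length=600_000,
    n_tri=12, n_ctss=80, n_inactive=20,
)
genome, genes, truth = t.generate_genome(cfg)
plus_track, minus_track, _, _ = t.simulate_strand_transcription(truth, genome)

tri_tss = [
    t.GenomicInterval(g.chrom, g.tss, g.tss + 1, g.strand, g.gene_id)
    for g in truth.genes_of_class("tri")
]
ctss = [
    t.GenomicInterval(g.chrom, g.tss, g.tss + 1, g.strand, g.gene_id)
    for g in truth.genes_of_class("ctss")
]
matched = t.match_sample(ctss, len(tri_tss), seed=1)

mat = t.build_matrix(tri_tss, plus_track, genome, flank_up=1500, flank_down=1500,
                     bin_size=50, anchor="start")
agg = t.aggregate(mat)
center = len(agg["median"]) // 2
print(f"profile matrix: {mat.values.shape[0]} regions x {mat.values.shape[1]} bins")
print(f"median plus-strand signal at TSS bin: {agg['median'][center]:.2f} "
      f"+- {agg['se'][center]:.3f} (n={agg['n'][center]})")

win = [t.GenomicInterval(r.chrom, r.start - 500, r.start + 500) for r in tri_tss]
ctl_win = [t.GenomicInterval(r.chrom, r.start - 500, r.start + 500) for r in matched]
cmp = t.compare_region_groups(win, ctl_win, plus_track, sub_window=100)
print()
print(f"TRI vs matched cTSS plus-strand summaries: medians "
      f"{cmp['median_a']:.2f} vs {cmp['median_b']:.2f}, rank-sum P = {cmp['p_value']:.3g}")
print()
print("TRI loci carry extra plus-strand signal from divergent partners and")
print("unannotated antisense transcription, so their summaries exceed the")
print("size-matched control TSSs; the matched sample keeps n equal.")
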