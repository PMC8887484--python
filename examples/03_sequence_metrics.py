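"""GC content, GC skew, and G-quadruplex propensity at TRI vs control TSSs.

TRI-class promoters in the synthetic genome carry elevated GC, positive
downstream GC skew on the coding strand, and planted G-run tracts; control
promoters have moderate unskewed GC. G4 propensity uses run-length-based
per-base scores (+/- min(run, 4)) averaged over 25 nt windows, hit
threshold 1.4.
"""
import numpy as np

import tripnseq as t

cfg = t.SimulationConfig(
    seed=7, n_chromosomes=2, chrom_length=600_000,
    n_tri=12, n_ctss=80, n_inactive=20,
)
genome, genes, truth = t.generate_genome(cfg)


def promoter_stats(gene_class):
    gc, skew, g4 = [], [], []
    for g in truth.genes_of_class(gene_class):
        lo, hi = g.tss - 200, g.tss + 200
        seq = genome.sequence(g.chrom, lo, hi)
        _, frac = t.gc_percent(seq, window=len(seq))
        gc.append(frac[0])
        _, sk = t.gc_skew(seq, window=len(seq))
        skew.append(sk[0] if g.strand == "+" else -sk[0])
        _, summary = t.find_g4([t.GenomicInterval(g.chrom, lo, hi)], genome)
        g4.append(summary[0][0])
    return np.mean(gc), np.nanmean(skew), np.mean(g4)


for cls, label in (("tri", "TRI promoters"), ("ctss", "control promoters")):
    gc, skew, g4 = promoter_stats(cls)
    print(f"{label:18s} GC={gc:.2f}  coding-strand GC skew={skew:+.2f}  "
          f"G4 hits per 400 bp={g4:.2f}")
print()
print("TRI promoters are more GC-rich, show positive coding-strand GC skew")
print("downstream of the TSS, and carry G4-prone G-run tracts; controls do not.")
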