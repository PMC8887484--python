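"""Variant-class enrichment at TRI genes vs sampled control genes.

The synthetic genome plants a 2x deletion rate in TRI gene bodies (0.4 vs
0.2 deletions per kb) with equal SBS and insertion rates everywhere. The
enrichment test counts variants per class over the TRI gene set and
compares with 999 random same-size draws from the control gene pool.
"""
import tripnseq as t

cfg = t.SimulationConfig(
    seed=11, n_chromosomes=4, chrom_length=1_500_000,
    n_tri=100, n_ctss=300, n_inactive=50,
)
genome, genes, truth = t.generate_genome(cfg)
variants = t.simulate_variants(truth, genome, seed=11)
print(f"simulated variants: {len(variants)}")

query = [g.interval() for g in truth.genes_of_class("tri")]
pool = [g.interval() for g in truth.genes_of_class("ctss")]
results = t.variant_enrichment(query, pool, variants, n_iter=999, seed=11)
for cls, r in results.items():
    print(f"  {cls:10s} observed={r.observed:5.0f}  null={r.null_mean:7.1f}"
          f"  fold={r.fold:.2f}  P={r.p:.3f}")
print()
print("Deletions come back close to the planted 2x rate with P at the")
print("999-draw floor, while SBS and insertions (equal rates) stay near fold 1.")
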