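"""Call TRI loci on a small synthetic dataset with planted truth.

Simulates a 2 x 600 kb genome with 12 planted TRIs (BrdU+ enrichment fold 4
over BrdU- controls, 3+3 replicates), runs the full discovery pipeline
(candidate peaks -> differential beta-binomial test -> sliding-window TSS
scan -> combine/merge at FDR <= 0.05) and scores the calls against truth.
"""
import tripnseq as t

cfg = t.SimulationConfig(
    seed=42, n_chromosomes=2, chrom_length=600_000,
    n_tri=12, n_ctss=80, n_inactive=20, fragments_per_replicate=80_000,
)
genome, genes, truth = t.generate_genome(cfg)
fragments = t.simulate_tripn_fragments(cfg, truth, genome)
result = t.run_discovery(fragments, genes, genome)
scores = t.evaluate_against_truth(result, truth.tri_loci)

print(f"planted TRIs:        {len(truth.tri_loci)}")
print(f"called TRI loci:     {len(result.loci)} (all FDR <= 0.05)")
print(f"control TSSs (cTSS): {len(result.ctss)}")
print(f"sensitivity:         {scores['sensitivity']:.2f}")
print(f"empirical FDR:       {scores['fdr']:.3f}")
print(f"NB dispersion (MoM): {result.dispersion:.4f}")
print()
print("first three loci (chrom:start-end, FDR, associated genes):")
for locus in result.loci[:3]:
    iv = locus.interval
    print(f"  {iv.chrom}:{iv.start}-{iv.end}  FDR={locus.fdr:.2e}  {locus.genes}")
print()
print("Sensitivity ~1 and empirical FDR well below 0.05 mean the planted")
print("BrdU+/BrdU- enrichment is recovered essentially without false calls.")
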