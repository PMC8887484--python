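# Methods

This note documents the models, estimators, numerical choices and known
limitations of `tripnseq`. Notation: BrdU+ samples are "experimental",
BrdU− samples "control"; all coordinates are 0-based half-open (BED
convention), with 1-based VCF positions converted at the parser boundary.

## TRI discovery

### Candidate peaks

Fragment pileups (count of fragments overlapping each 50 bp bin) are pooled
across experimental replicates and tested per bin against a Poisson null
with λ_local = max(λ_genome, λ_5kb, λ_10kb), where the local rates come
from the pooled control pileup scaled to experimental depth (or, with no
control, from the experiment-wide rate alone — local rates from the
experiment itself would cancel the very peaks being sought). Bin p-values
are BH-corrected genome-wide; bins at q ≤ 0.05 are merged within 200 bp and
peaks shorter than 150 bp dropped. This caller is deliberately simple: the
pipeline's accuracy target is recovery of planted truth plus the downstream
differential test, not numeric agreement with any external peak caller.

### Differential enrichment test

Windows (candidate peaks, and the TSS sliding-window sets) are tested with
a pooled conditional test. With library sizes lib_j, experimental pooled
count k and total t = k + control pooled count:

- null proportion p₀ = Σlib₊/(Σlib₊ + Σlib₋)
- one-sided enrichment p = P(X ≥ k), X ~ BetaBinomial(t, a, b) with
  a = p₀·m/α, b = (1 − p₀)·m/α, where m is the number of samples and α the
  common negative-binomial dispersion (Var = μ + αμ²)
- log2 fold change log2((k/Σlib₊ + c)/((t − k)/Σlib₋ + c)) with pseudocount
  c = 0.5/min(lib); t = 0 gives p = 1, log2FC = 0

Rationale: if per-replicate counts are gamma-Poisson with equal means and
equal libraries, the conditional law of k given t is *exactly*
beta-binomial with per-condition shapes R/α (gamma shapes add), so the test
is the conditional version of the usual NB model with no asymptotics. With
unequal libraries the shape split a = p₀·m/α is an approximation; libraries
from a matched protocol are near-equal in practice. As α → 0 the test
reduces to binomial(t, p₀); computed p-values are floored at 1e−300 because
a one-sided tail probability is never mathematically zero.

α is estimated once per run by method of moments from replicate-level
within-condition variance of count proportions p̂ = k_j/lib_j: across all
windows with t ≥ 10, α̂ = Σ(s²_w − p̄_w(1−p̄_w)·mean(1/lib)) / Σp̄²_w,
clipped at 0. The ratio-of-means form pools degrees of freedom across
windows (single-window moment estimates with 2 df are far too noisy) and is
consistent even when some windows carry true between-condition enrichment,
because only within-condition variance enters. On null simulations at the
default conditions the estimate recovers the generating dispersion to a few
percent and the test's empirical P(p ≤ 0.05) sits at 0.048–0.053 over
10 000 windows.

### TSS sliding-window scan and merge rule

Each TSS contributes windows [TSS − 1000 + 100k, … + 1000 bp) for offsets
k = 0…10; each offset set is counted, tested and BH-corrected independently
(a pooled-FDR mode exists for sensitivity analysis). Overlapping windows
across nearby TSSs within one set are merged before counting so no fragment
is tested twice within a set. All members (peaks and windows) at FDR ≤ 0.05
are unioned and merged (bookended intervals merge at gap 0); each merged
locus keeps the *highest* member FDR — a deliberately conservative
provenance rule — and its full member list. Genes are associated when their
TSS lies within ±1.5 kb of the locus center; multiple genes per locus are
expected (divergent pairs). The cTSS control set is every active TSS
(pooled fragment count above a configurable floor, default > 0, in the
±1 kb TSS window) not associated with any TRI.

Window length default is 1000 bp. The procedure is also run in an 800 bp
variant in some published workflows; the parameter is exposed
(`window_length`) rather than fixed.

## Characterization statistics

- **RFD** = (R − F)/(R + F) per bin of strand-split Okazaki-fragment
  counts. Bins with R + F = 0 are missing (NaN), not 0: zero is a
  meaningful "balanced forks" value and must not be conflated with absence
  of data. Convention: rightward-moving forks yield reverse-strand Okazaki
  fragments, so RFD = +1 means purely rightward replication.
- **Timing log2 ratio**: per 100 bp bin, log2((S + c)/(G0 + c)) of
  RPM-normalized coverage with pseudocount c = 0.1 RPM, then a centered
  NaN-aware running mean over 500 bp. Blacklisted bins stay missing.
- **GC skew / GC fraction**: (G − C)/(G + C) and (G + C)/(A + C + G + T)
  over 200 bp sliding windows at 1 bp steps; the value is assigned to the
  window center (start + window//2 — floor-centering for even windows);
  windows with no informative bases are missing; N excluded from the GC
  denominator.
- **G4 propensity**: per-base scores +min(L, 4) for each G in a maximal
  G-run of length L, −min(L, 4) for C-runs, 0 otherwise; the windowed score
  is the arithmetic mean over 25 nt. Windows with |score| ≥ 1.4 qualify;
  *consecutive* qualifying window starts are merged into one hit spanning
  their union (hit score = extremal window mean), since a single G4 tract
  qualifies many overlapping windows. Unmerged per-window counting is
  available behind a flag. Scores negate under complementation, so the sign
  encodes the G4-bearing strand.
- **Orientation classes**: upstream/downstream are defined relative to the
  focal TSS's own strand and partner distance measured TSS-to-TSS. A
  divergent pair needs an opposite-strand annotated TSS within 3 kb
  upstream with both TSSs overlapping own-strand transcription peaks
  (±500 bp TSS window, ≥1 bp overlap); convergent, the same downstream;
  single-bidirectional needs no annotated neighbor within 3 kb but signal
  on both strands; anything else is unclassified. When both divergent and
  convergent partners qualify, divergent wins (it is the biologically
  foregrounded arrangement) and all qualifying partners are retained in the
  evidence field.
- **Profiles**: point-anchored matrices hold per-bin mean track signal per
  region; blacklisted or off-chromosome regions are excluded whole (not
  masked), so every row is complete. Aggregation is per-column median and
  SE = sd/√n over non-missing rows. Scaled gene-body profiles resample the
  body to a fixed number of length-proportional bins with natively binned
  flanks and are read in transcription direction; point-anchored profiles
  default to no strand flip, scaled-body profiles to flipped — both
  configurable, since conventions differ between plotting tools.
- **Region-group comparison**: per region, the median track value per
  sub-window, then the mean across sub-windows (empty sub-windows
  excluded); groups compared with the two-sided Wilcoxon rank-sum test —
  exact enumeration of all labelings (midranks for ties) for pooled n ≤ 16,
  tie-corrected normal approximation with continuity correction above.

## Resampling inference

Empirical P = (r + 1)/(n + 1), where r counts null draws at least as
extreme as the observation. Ties count as extreme (conservative; P can
never be 0, matching the formula's floor of 1/(n + 1)). Fold enrichment is
observed/mean(null) by default with a median(null) variant available, since
"fold over random chance" admits both readings. All resampling uses
explicit integer-seeded PCG64 generators; results are deterministic given
(inputs, seed) and independent of input ordering.

The workspace overlap test flattens (merges) the workspace, clips both
query and annotations into it, and re-places each query segment — length
preserved, unsplit — uniformly within the concatenated workspace
coordinates; placed segments may overlap one another. This trades the
exactness of non-overlapping placement for simplicity and an analytic null:
the expected overlap fraction equals the annotation coverage fraction of
the workspace, which the implementation matches within Monte-Carlo error.
A query segment longer than the whole workspace is an error naming the
segment.

## Synthetic data: what it emulates and what it does not

The generator plants, at desk scale, the data properties the pipeline
targets. Defaults (all frozen as the package's study conditions): 4
chromosomes × 5 Mb; 2000 genes — 150 TRI-class, 1350 active controls, 500
inactive — mirroring a ~1:9 TRI:control ratio; 3+3 replicates of 10⁶
fragments (library sizes exact by construction, background absorbing the
gene-count fluctuation); fragment lengths uniform 200–500 bp; NB dispersion
0.05 (a typical ChIP replicate value; the assay's real dispersion is not
published); planted BrdU+ enrichment fold 4 at TRI promoters (no measured
fold exists to copy; 4 gives comfortable but not trivial signal at 10⁶
fragments). TRI promoters get a bimodal occupancy profile (two flanking
peaks at ±500 bp), controls a single central peak, echoing the flanking
vs central polymerase signal patterns the two locus classes show. TRI
promoter sequence is GC-rich (≈65%) with positive coding-strand GC skew
downstream of the TSS and planted G-run/G4 tracts; control promoters are
GC-moderate and unskewed. A third of TRI genes get divergent partners, a
third convergent partners (TSS-to-TSS distance 0.8–2.5 kb), a third
unannotated antisense signal only. Okazaki fragments follow an
origin-firing model: each origin fires independently with its efficiency,
adjacent fired origins' forks meet at their midpoint, and a fragment at x
is reverse-strand iff replicated rightward; the analytic marginal
(`expected_rfd`) enumerates firing patterns and serves as the oracle.
Variants are Poisson per kb per class territory with deletions at 2× in
TRI gene bodies (0.4 vs 0.2/kb); class territories are made disjoint
(TRI > control > intergenic) before placement so overlapping gene bodies do
not locally double rates.

Not emulated: read-level sequence and quality simulation, PCR duplicates,
mappability and blacklist structure of real genomes, GC-dependent coverage
bias, chromatin-state-dependent background, multi-allelic variant sites.
Consequently, passing tests demonstrate correctness of the statistical
machinery and recoverability of planted effects under NB noise — not
robustness to every artifact of real sequencing data.

## Problem sizes and determinism

The default synthetic study (20 Mb, 6 × 10⁶ fragments) runs discovery in
well under a minute; the acceptance script and full test suite each run in
seconds to a few minutes on one CPU. These sizes were chosen so a complete
verification cycle is a desk-scale operation while keeping per-window
counts (hundreds) in the regime where the beta-binomial test's calibration
matters. All generators are PCG64 with explicit integer seeds; identical
config + seed reproduces byte-identical outputs.

## Known limitations

- Library normalization is by total fragment count only (no trimmed-mean
  or loess normalization); appropriate for matched-protocol genome-wide IP
  libraries, inadequate if composition differs grossly between conditions.
- The beta-binomial shape split under unequal libraries is approximate
  (see above); two-group designs only.
- The merge rule "highest FDR kept" is conservative by construction; an
  alternative reading (per-duplicate-window rather than per-locus) is not
  implemented.
- `map_signal_summary` allows a final partial sub-window rather than
  requiring exact division; its summary therefore weights a trailing
  partial window equally with full ones.
- The workspace randomization is unconditional uniform placement; no
  GC- or isochore-matched null is provided.
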