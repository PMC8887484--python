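"""Synthetic genome, fragment, transcription, Okazaki-fragment and variant
simulation with known planted truth.

The generator realizes, at desk scale, the data properties the pipeline is
built for: replicate fragment counts with negative-binomial noise and planted
BrdU+ enrichment at TRI promoters, strand-specific nascent-transcription
peaks in divergent/convergent/single-bidirectional arrangements,
Okazaki-fragment strand counts from a planted origin/termination fork model,
GC-skewed G4-bearing TRI promoter sequences, and variant calls with an
elevated deletion rate in TRI gene bodies. All outputs are deterministic
given the config seed (PCG64 integer-state generator).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    FragmentSet,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    CoverageTrack,
    ValidationError,
)
from .metrics import StrandCounts, revcomp
from .variants import VariantRecord

ORIENTATIONS = ("divergent_pair", "convergent_pair", "single_bidirectional")


def _default_variant_rates() -> dict[str, dict[str, float]]:
    # per-kb Poisson rates per region class; deletions planted at 2x in TRI
    # gene bodies
    return {
        "sbs": {"tri_gene": 0.5, "control_gene": 0.5, "intergenic": 0.5},
        "insertion": {"tri_gene": 0.1, "control_gene": 0.1, "intergenic": 0.1},
        "deletion": {"tri_gene": 0.4, "control_gene": 0.2, "intergenic": 0.2},
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the target data shape at 1/10 gene count: 4 chromosomes
    x 5 Mb, 2000 genes of which 150 are TRI-class, 1350 active controls and
    500 inactive; 3+3 replicates of 1e6 fragments each, fragment lengths
    uniform in 200-500 bp, negative-binomial dispersion 0.05 and a planted
    BrdU+ enrichment fold of 4 at TRI promoters.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    n_tri: int = 150
    n_ctss: int = 1350
    n_inactive: int = 500
    enrichment_fold: float = 4.0
    replicates: int = 3
    fragments_per_replicate: int = 1_000_000
    fragment_length: tuple[int, int] = (200, 500)
    nb_dispersion: float = 0.05
    promoter_mean: float = 150.0
    tri_flank: int = 1000
    origins_per_chrom: int = 3
    origin_efficiency: float = 0.8
    variant_rates: dict[str, dict[str, float]] = field(
        default_factory=_default_variant_rates
    )

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_tri", "n_ctss",
            "replicates", "fragments_per_replicate",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_inactive < 0:
            raise ValidationError("n_inactive must be >= 0")
        if self.enrichment_fold < 1:
            raise ValidationError("enrichment_fold must be >= 1")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        for cls_rates in self.variant_rates.values():
            for v in cls_rates.values():
                if v < 0:
                    raise ValidationError("variant rates must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_tri + self.n_ctss + self.n_inactive


@dataclass
class SyntheticTruth:
    """Planted ground truth for every downstream stage."""

    tri_loci: list[GenomicInterval]
    genes: list[GeneAnnotation]
    gene_classes: dict[str, str]  # tri | ctss | inactive | partner
    orientation: dict[str, str]  # TRI gene id -> orientation class
    partners: dict[str, str]  # focal gene id -> partner gene id
    origins: dict[str, list[tuple[int, float]]]
    variant_rates: dict[str, dict[str, float]]

    def genes_of_class(self, cls: str) -> list[GeneAnnotation]:
        return [g for g in self.genes if self.gene_classes[g.gene_id] == cls]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, *key])))


def _random_sequence(rng: np.random.Generator, n: int, probs: Sequence[float]) -> np.ndarray:
    """Random base array ('A','C','G','T' order of probs)."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    cum = np.cumsum(probs)
    cum = cum / cum[-1]
    return bases[np.searchsorted(cum, rng.random(n), side="right")]


# base probabilities (A, C, G, T)
_BG = (0.30, 0.20, 0.20, 0.30)
_CTSS = (0.25, 0.25, 0.25, 0.25)
_TRI_UP = (0.175, 0.325, 0.325, 0.175)  # GC-rich, symmetric
_TRI_DOWN = (0.20, 0.18, 0.42, 0.20)  # GC-rich with positive GC skew
_G4_TRACT = "GGGAGGGAGGGAGGG" + "GGC" * 8


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeModel, list[GeneAnnotation], SyntheticTruth]:
    """Genome sequence, gene annotations, and planted truth.

    TRI-class promoters receive elevated GC content, positive GC skew
    downstream of the TSS on the coding strand, and planted G-run tracts;
    control (cTSS-class) promoters get moderate, unskewed GC; inactive genes
    keep the background composition. Divergent/convergent TRI genes receive
    an opposite-strand partner gene with a TSS 0.8-2.5 kb away.
    """
    cfg = config
    rng = _rng(cfg.seed, 1)
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    spacing = cfg.chrom_length // (per_chrom + 1)
    if spacing < 9000:
        raise ValidationError(
            "gene count too large for genome size (need >= 9 kb spacing)"
        )
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    seqs = {
        c: _random_sequence(rng, cfg.chrom_length, _BG) for c in chroms
    }

    # gene slots and class assignment
    slots = []
    for c in chroms:
        for i in range(per_chrom):
            if len(slots) < cfg.n_genes:
                jitter = int(rng.integers(-1000, 1001))
                slots.append((c, (i + 1) * spacing + jitter))
    classes = (
        ["tri"] * cfg.n_tri + ["ctss"] * cfg.n_ctss + ["inactive"] * cfg.n_inactive
    )
    order = rng.permutation(cfg.n_genes)
    genes: list[GeneAnnotation] = []
    gene_classes: dict[str, str] = {}
    orientation: dict[str, str] = {}
    partners: dict[str, str] = {}
    tri_loci: list[GenomicInterval] = []
    tri_seen = 0

    for idx, (chrom, tss) in enumerate(slots):
        cls = classes[order[idx]]
        gid = f"g{idx:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(2000, 8001))
        if strand == "+":
            start, end = tss, min(tss + length, cfg.chrom_length)
        else:
            start, end = max(0, tss - length + 1), tss + 1
        genes.append(GeneAnnotation(gid, chrom, start, end, strand))
        gene_classes[gid] = cls
        if cls == "tri":
            orient = ORIENTATIONS[tri_seen % len(ORIENTATIONS)]
            tri_seen += 1
            orientation[gid] = orient
            tri_loci.append(
                GenomicInterval(
                    chrom,
                    max(0, tss - cfg.tri_flank),
                    min(cfg.chrom_length, tss + cfg.tri_flank),
                    strand,
                    gid,
                    cfg.enrichment_fold,
                )
            )
            if orient in ("divergent_pair", "convergent_pair"):
                d = int(rng.integers(800, 2501))
                sign = -1 if strand == "+" else 1  # upstream direction
                if orient == "convergent_pair":
                    sign = -sign
                p_tss = tss + sign * d
                p_strand = "-" if strand == "+" else "+"
                p_len = int(rng.integers(2000, 5001))
                if p_strand == "+":
                    ps, pe = p_tss, min(p_tss + p_len, cfg.chrom_length)
                else:
                    ps, pe = max(0, p_tss - p_len + 1), p_tss + 1
                pid = f"{gid}_p"
                genes.append(GeneAnnotation(pid, chrom, ps, pe, p_strand))
                gene_classes[pid] = "partner"
                partners[gid] = pid

    # promoter sequence planting
    for g in genes:
        cls = gene_classes[g.gene_id]
        if cls == "inactive":
            continue
        seq = seqs[g.chrom]
        tss = g.tss
        sgn = 1 if g.strand == "+" else -1
        if cls in ("ctss", "partner"):
            lo = max(0, tss - 500)
            hi = min(cfg.chrom_length, tss + 500)
            seq[lo:hi] = _random_sequence(rng, hi - lo, _CTSS)
            continue
        # TRI promoter: GC-rich upstream, skewed + G4 tract downstream
        if g.strand == "+":
            up_lo, up_hi = max(0, tss - 500), tss
            dn_lo, dn_hi = tss, min(cfg.chrom_length, tss + 500)
        else:
            up_lo, up_hi = tss + 1, min(cfg.chrom_length, tss + 501)
            dn_lo, dn_hi = max(0, tss - 499), tss + 1
        seq[up_lo:up_hi] = _random_sequence(rng, up_hi - up_lo, _TRI_UP)
        dn = _random_sequence(rng, dn_hi - dn_lo, _TRI_DOWN)
        tract = _G4_TRACT
        if g.strand == "-":
            dn = np.frombuffer(
                revcomp(dn.tobytes().decode()).encode(), dtype="S1"
            ).copy()
            toff = (dn_hi - dn_lo) - 50 - len(tract)
            tract = revcomp(tract)
        else:
            toff = 50
        if 0 <= toff and toff + len(tract) <= len(dn):
            dn[toff : toff + len(tract)] = np.frombuffer(
                tract.encode(), dtype="S1"
            )
        seq[dn_lo:dn_hi] = dn

    # replication origins
    origins: dict[str, list[tuple[int, float]]] = {}
    for c in chroms:
        pos = np.linspace(0, cfg.chrom_length, cfg.origins_per_chrom + 2)[1:-1]
        origins[c] = [(int(p), cfg.origin_efficiency) for p in pos]

    sequences = {c: seqs[c].tobytes().decode("ascii") for c in chroms}
    genome = GenomeModel({c: cfg.chrom_length for c in chroms}, sequences)
    truth = SyntheticTruth(
        tri_loci=tri_loci,
        genes=genes,
        gene_classes=gene_classes,
        orientation=orientation,
        partners=partners,
        origins=origins,
        variant_rates=config.variant_rates,
    )
    return genome, genes, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mean))


def simulate_tripn_fragments(
    config: SimulationConfig,
    truth: SyntheticTruth,
    genome: GenomeModel,
) -> list[FragmentSet]:
    """Replicate fragment sets for BrdU+ and BrdU- conditions.

    Per active gene the expected promoter fragment count is
    ``promoter_mean``; at planted TRIs the BrdU+ expectation is multiplied by
    the enrichment fold. Counts are negative-binomial with the configured
    dispersion; fragment midpoints follow the promoter occupancy profile
    (bimodal flanking peaks for TRI-class promoters, a central peak
    otherwise); remaining fragments are uniform background, so each library
    size equals ``fragments_per_replicate`` exactly.
    """
    cfg = config
    active = [g for g in truth.genes if truth.gene_classes[g.gene_id] != "inactive"]
    tss = np.array([g.tss for g in active])
    chrom_of = np.array([g.chrom for g in active])
    is_tri = np.array(
        [truth.gene_classes[g.gene_id] == "tri" for g in active]
    )
    chroms = genome.chroms
    chrom_len = np.array([genome.chrom_lengths[c] for c in chroms])
    lmin, lmax = cfg.fragment_length
    out: list[FragmentSet] = []
    for ci, cond in enumerate(("BrdU+", "BrdU-")):
        for rep in range(cfg.replicates):
            rng = _rng(cfg.seed, 2, ci, rep)
            mu = np.full(len(active), cfg.promoter_mean)
            if cond == "BrdU+":
                mu[is_tri] *= cfg.enrichment_fold
            counts = _nb_draw(rng, mu, cfg.nb_dispersion)
            total_gene = int(counts.sum())
            n_bg = cfg.fragments_per_replicate - total_gene
            if n_bg < 0:
                raise ValidationError(
                    "promoter fragment mass exceeds library size; lower "
                    "promoter_mean or raise fragments_per_replicate"
                )
            centers = np.repeat(tss, counts)
            gchrom = np.repeat(chrom_of, counts)
            gtri = np.repeat(is_tri, counts)
            # occupancy profiles: bimodal +-500 for TRI, central otherwise
            offs = rng.normal(0.0, 150.0, size=len(centers))
            side = rng.integers(0, 2, size=len(centers)) * 2 - 1
            offs = np.where(gtri, offs + side * 500, offs)
            mids = centers + offs.astype(np.int64)
            # background, uniform over the genome
            bg_chrom_idx = rng.choice(
                len(chroms), size=n_bg, p=chrom_len / chrom_len.sum()
            )
            bg_mid = (rng.random(n_bg) * chrom_len[bg_chrom_idx]).astype(np.int64)
            all_chrom = np.concatenate([gchrom, np.array(chroms)[bg_chrom_idx]])
            all_mid = np.concatenate([mids, bg_mid])
            lengths = rng.integers(lmin, lmax + 1, size=len(all_mid))
            ch_arr = np.array(chroms)
            sort_idx = np.argsort(ch_arr)
            cidx = sort_idx[np.searchsorted(ch_arr[sort_idx], all_chrom)]
            starts = np.clip(
                all_mid - lengths // 2, 0, chrom_len[cidx] - lengths
            )
            ends = starts + lengths
            out.append(
                FragmentSet(
                    sample_id=f"{'exp' if cond == 'BrdU+' else 'ctl'}{rep + 1}",
                    condition=cond,
                    replicate=rep,
                    chroms=all_chrom,
                    starts=starts,
                    ends=ends,
                )
            )
    return out


def simulate_strand_transcription(
    truth: SyntheticTruth,
    genome: GenomeModel,
    bin_size: int = 50,
    peak_length: int = 800,
    antisense_length: int = 600,
) -> tuple[CoverageTrack, CoverageTrack, list[GenomicInterval], list[GenomicInterval]]:
    """Plus/minus nascent-transcription tracks and strandwise peak sets.

    Every active gene gets an own-strand peak downstream of its TSS;
    single-bidirectional TRI genes additionally get an opposite-strand peak
    just upstream with no annotated partner; inactive genes stay silent.
    """
    plus_peaks: list[GenomicInterval] = []
    minus_peaks: list[GenomicInterval] = []

    def add(chrom: str, start: int, end: int, strand: str, name: str) -> None:
        start = max(0, start)
        end = min(genome.chrom_lengths[chrom], end)
        if start < end:
            (plus_peaks if strand == "+" else minus_peaks).append(
                GenomicInterval(chrom, start, end, strand, name)
            )

    for g in truth.genes:
        cls = truth.gene_classes[g.gene_id]
        if cls == "inactive":
            continue
        if g.strand == "+":
            add(g.chrom, g.tss, g.tss + peak_length, "+", g.gene_id)
        else:
            add(g.chrom, g.tss - peak_length + 1, g.tss + 1, "-", g.gene_id)
        if truth.orientation.get(g.gene_id) == "single_bidirectional":
            if g.strand == "+":
                add(g.chrom, g.tss - antisense_length, g.tss, "-", g.gene_id + "_as")
            else:
                add(g.chrom, g.tss + 1, g.tss + 1 + antisense_length, "+", g.gene_id + "_as")

    def rasterize(peaks: list[GenomicInterval]) -> CoverageTrack:
        track = CoverageTrack.zeros(genome, bin_size)
        for p in peaks:
            arr = track.data[p.chrom]
            lo = p.start // bin_size
            hi = -(-p.end // bin_size)
            arr[lo:hi] = 1.0
        return track

    return rasterize(plus_peaks), rasterize(minus_peaks), plus_peaks, minus_peaks


# ---------------------------------------------------------------------------
# OK-seq fork model
# ---------------------------------------------------------------------------

def _subset_patterns(m: int) -> np.ndarray:
    """All non-empty firing patterns for m origins as a (2^m - 1, m) bool array."""
    n = 2**m
    bits = ((np.arange(1, n)[:, None] >> np.arange(m)) & 1).astype(bool)
    return bits


def _rightward_given_fired(
    x: np.ndarray, fired: np.ndarray
) -> np.ndarray:
    """For sorted fired origin positions, is x replicated by a rightward fork?

    Forks from adjacent fired origins meet at their midpoint; positions left
    of the leftmost fired origin are replicated leftward, right of the
    rightmost rightward.
    """
    i = np.searchsorted(fired, x, side="right")
    right = np.ones(len(x), dtype=bool)
    right[i == 0] = False
    inner = (i > 0) & (i < len(fired))
    if inner.any():
        L = fired[i[inner] - 1]
        R = fired[i[inner]]
        right[inner] = x[inner] < (L + R) / 2.0
    return right


def expected_rfd(
    origins: Sequence[tuple[int, float]], positions: np.ndarray
) -> np.ndarray:
    """Analytic expected RFD = 2*f_R - 1 from the planted fork model.

    f_R(x) marginalizes over origin-firing patterns (each origin fires
    independently with its efficiency), conditioned on at least one origin
    firing; with no origins forks are balanced and RFD is 0.
    """
    positions = np.asarray(positions, dtype=float)
    if len(origins) == 0:
        return np.zeros(len(positions))
    pos = np.array([p for p, _ in origins], dtype=float)
    eff = np.array([e for _, e in origins], dtype=float)
    order = np.argsort(pos)
    pos, eff = pos[order], eff[order]
    patterns = _subset_patterns(len(pos))
    probs = np.prod(np.where(patterns, eff, 1 - eff), axis=1)
    probs = probs / probs.sum()
    f_r = np.zeros(len(positions))
    for pat, pr in zip(patterns, probs):
        if pr == 0:
            continue
        f_r += pr * _rightward_given_fired(positions, pos[pat])
    return 2.0 * f_r - 1.0


def simulate_okseq(
    truth: SyntheticTruth,
    genome: GenomeModel,
    depth_per_mb: int = 10_000,
    bin_size: int = 1000,
    seed: int | None = None,
) -> StrandCounts:
    """Okazaki-fragment strand counts per bin from the planted fork model.

    Convention: rightward forks yield reverse-strand Okazaki fragments, so
    the expected RFD at x equals 2*f_R(x) - 1. With no planted origins forks
    are balanced (each fragment's strand is a fair coin).
    """
    if depth_per_mb <= 0:
        raise ValidationError("depth must be positive")
    for ors in truth.origins.values():
        for _, e in ors:
            if not (0 < e <= 1):
                raise ValidationError("origin efficiencies must be in (0, 1]")
    rng = _rng(seed if seed is not None else 0, 3)
    fwd: dict[str, np.ndarray] = {}
    rev: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths.items():
        nbins = -(-length // bin_size)
        n = int(round(depth_per_mb * length / 1e6))
        x = rng.random(n) * length
        origins = truth.origins.get(chrom, [])
        if not origins:
            right = rng.random(n) < 0.5
        else:
            pos = np.array(sorted(p for p, _ in origins), dtype=float)
            eff = np.array(
                [e for p, e in sorted(origins)], dtype=float
            )
            patterns = _subset_patterns(len(pos))
            probs = np.prod(np.where(patterns, eff, 1 - eff), axis=1)
            probs = probs / probs.sum()
            pat_idx = rng.choice(len(patterns), size=n, p=probs)
            right = np.zeros(n, dtype=bool)
            for pi in range(len(patterns)):
                sel = pat_idx == pi
                if sel.any():
                    right[sel] = _rightward_given_fired(
                        x[sel], pos[patterns[pi]]
                    )
        bins = (x // bin_size).astype(np.int64)
        rev[chrom] = np.bincount(bins[right], minlength=nbins).astype(float)
        fwd[chrom] = np.bincount(bins[~right], minlength=nbins).astype(float)
    return StrandCounts(bin_size, fwd, rev)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def simulate_variants(
    truth: SyntheticTruth,
    genome: GenomeModel,
    rates: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
) -> list[VariantRecord]:
    """SBS/insertion/deletion calls placed by per-class Poisson rates per kb.

    Region classes are TRI gene bodies, control (cTSS) gene bodies, and the
    intergenic remainder. Reference alleles are read from the genome
    sequence so every record round-trips through VCF.
    """
    rates = rates if rates is not None else truth.variant_rates
    for cls_rates in rates.values():
        for v in cls_rates.values():
            if v < 0:
                raise ValidationError("variant rates must be >= 0")
    rng = _rng(seed if seed is not None else 0, 4)

    # class territories are made disjoint (tri > control > intergenic) so
    # overlapping gene bodies do not locally double the placement rate
    from .core import merge_intervals, subtract_intervals

    tri_regions = merge_intervals([g.interval() for g in truth.genes_of_class("tri")])
    ctl_regions = subtract_intervals(
        [g.interval() for g in truth.genes_of_class("ctss")], tri_regions
    )
    genic = merge_intervals([g.interval() for g in truth.genes])
    whole = [
        GenomicInterval(c, 0, n) for c, n in genome.chrom_lengths.items()
    ]
    regions: dict[str, list[GenomicInterval]] = {
        "tri_gene": tri_regions,
        "control_gene": ctl_regions,
        "intergenic": subtract_intervals(whole, genic),
    }

    records: list[VariantRecord] = []
    for vtype, cls_rates in rates.items():
        for cls, rate in cls_rates.items():
            if rate == 0:
                continue
            for iv in regions[cls]:
                n = rng.poisson(rate * len(iv) / 1000.0)
                if n == 0:
                    continue
                positions = iv.start + (rng.random(n) * (len(iv) - 6)).astype(int)
                for p in positions:
                    p = int(p)
                    if vtype == "sbs":
                        ref = genome.sequence(iv.chrom, p, p + 1)
                        alt = _BASES[
                            ( _BASES.index(ref) + int(rng.integers(1, 4)) ) % 4
                        ] if ref in _BASES else "A"
                        if ref not in _BASES:
                            continue
                    elif vtype == "insertion":
                        ref = genome.sequence(iv.chrom, p, p + 1)
                        ins = "".join(
                            _BASES[i] for i in rng.integers(0, 4, int(rng.integers(1, 4)))
                        )
                        alt = ref + ins
                    else:  # deletion
                        dlen = int(rng.integers(1, 4))
                        ref = genome.sequence(iv.chrom, p, p + 1 + dlen)
                        alt = ref[0]
                    records.append(VariantRecord(iv.chrom, p, ref, alt))
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


# ---------------------------------------------------------------------------
# Null window counts (differential-test calibration)
# ---------------------------------------------------------------------------

def simulate_null_window_counts(
    n_windows: int = 10_000,
    replicates: tuple[int, int] = (3, 3),
    mean_range: tuple[float, float] = (50.0, 500.0),
    dispersion: float = 0.05,
    library_size: int = 1_000_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window counts with no differential signal (enrichment fold 1).

    Returns (counts [n_windows x n_samples], library_sizes, is_experimental)
    with per-window means shared by every sample and NB noise at the given
    dispersion.
    """
    rng = _rng(seed, 5)
    n_exp, n_ctl = replicates
    n_samples = n_exp + n_ctl
    lo, hi = mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_windows))
    counts = np.empty((n_windows, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = _nb_draw(rng, mu, dispersion)
    libs = np.full(n_samples, library_size, dtype=np.int64)
    is_exp = np.array([True] * n_exp + [False] * n_ctl)
    return counts, libs, is_exp


# ---------------------------------------------------------------------------
# Standalone orientation truth set
# ---------------------------------------------------------------------------

def simulate_orientation_truth(
    n_per_class: int = 50, seed: int = 0, spacing: int = 10_000
) -> tuple[
    list[GeneAnnotation],
    list[GeneAnnotation],
    list[GenomicInterval],
    list[GenomicInterval],
    dict[str, str],
]:
    """A labeled TSS set covering all four orientation classes.

    Returns (focal genes, all annotated genes, plus peaks, minus peaks,
    truth labels). Focal loci are spaced far apart (default 10 kb) so the
    3 kb classification radius never mixes neighbors.
    """
    labels_cycle = list(ORIENTATIONS) + ["unclassified"]
    rng = _rng(seed, 6)
    chrom = "chrS"
    n_total = 4 * n_per_class
    length = (n_total + 2) * spacing
    focal: list[GeneAnnotation] = []
    annotated: list[GeneAnnotation] = []
    plus_peaks: list[GenomicInterval] = []
    minus_peaks: list[GenomicInterval] = []
    labels: dict[str, str] = {}

    def add_peak(start: int, end: int, strand: str, name: str) -> None:
        start, end = max(0, start), min(length, end)
        (plus_peaks if strand == "+" else minus_peaks).append(
            GenomicInterval(chrom, start, end, strand, name)
        )

    def own_peak(g: GeneAnnotation) -> None:
        if g.strand == "+":
            add_peak(g.tss, g.tss + 800, "+", g.gene_id)
        else:
            add_peak(g.tss - 799, g.tss + 1, "-", g.gene_id)

    slot = 0
    for cls_i, label in enumerate(labels_cycle):
        for k in range(n_per_class):
            tss = (slot + 1) * spacing
            slot += 1
            strand = "+" if (slot % 2) else "-"
            glen = 2000
            if strand == "+":
                g = GeneAnnotation(f"o{slot:04d}", chrom, tss, tss + glen, "+")
            else:
                g = GeneAnnotation(f"o{slot:04d}", chrom, tss - glen + 1, tss + 1, "-")
            focal.append(g)
            annotated.append(g)
            labels[g.gene_id] = label
            if label == "unclassified":
                # own-strand signal only, no partner: fails every rule
                own_peak(g)
                continue
            own_peak(g)
            if label == "single_bidirectional":
                if strand == "+":
                    add_peak(tss - 600, tss, "-", g.gene_id + "_as")
                else:
                    add_peak(tss + 1, tss + 601, "+", g.gene_id + "_as")
                continue
            d = int(rng.integers(800, 2501))
            upstream = -1 if strand == "+" else 1
            sign = upstream if label == "divergent_pair" else -upstream
            p_tss = tss + sign * d
            p_strand = "-" if strand == "+" else "+"
            if p_strand == "+":
                p = GeneAnnotation(
                    f"{g.gene_id}_p", chrom, p_tss, p_tss + glen, "+"
                )
            else:
                p = GeneAnnotation(
                    f"{g.gene_id}_p", chrom, p_tss - glen + 1, p_tss + 1, "-"
                )
            annotated.append(p)
            own_peak(p)
    return focal, annotated, plus_peaks, minus_peaks, labels
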