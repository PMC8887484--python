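"""TRI discovery: candidate peaks, replicate-aware differential enrichment,
sliding-window TSS scan, and the combine/merge rule.

The differential test is a pooled beta-binomial conditional test: with
experimental pooled count k out of t = k + control, the null is
k | t ~ beta-binomial(t, p0, rho) with p0 the library-size proportion and a
single overdispersion estimated per run by method of moments from
replicate-level within-condition proportion variance. For gamma-Poisson
(negative-binomial) replicate counts with equal libraries this conditional
distribution is exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import (
    FragmentSet,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    ValidationError,
    merge_intervals,
)


@dataclass
class DifferentialWindow:
    """A tested window: counts, fold change, one-sided p, and set-local FDR."""

    interval: GenomicInterval
    counts: np.ndarray  # per-sample raw counts
    log2_fold_change: float
    p_value: float
    fdr: float
    set_id: str

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if not (0 <= self.p_value <= 1 and 0 <= self.fdr <= 1):
            raise ValidationError("p/FDR outside [0,1]")


@dataclass
class TRILocus:
    """A merged significant region; FDR is the max over merged members."""

    interval: GenomicInterval
    fdr: float
    provenance: list[tuple[str, GenomicInterval, float]]  # (set id, member, fdr)
    genes: list[str] = field(default_factory=list)
    orientation: str | None = None

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValidationError("locus without provenance")


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_fragments(
    fragments: FragmentSet,
    windows: Sequence[GenomicInterval],
    mode: str = "overlap",
    genome: GenomeModel | None = None,
) -> np.ndarray:
    """Per-window fragment counts for one sample.

    In 'overlap' mode (default, mirrors consensus-site counting) a fragment
    is counted in every window it overlaps by >= 1 bp; in 'midpoint' mode it
    is counted only where its midpoint falls.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValidationError("mode must be 'overlap' or 'midpoint'")
    per = fragments.per_chrom()
    out = np.zeros(len(windows), dtype=np.int64)
    if genome is not None:
        for w in windows:
            genome.validate(w)
    mid_cache: dict[str, np.ndarray] = {}
    for i, w in enumerate(windows):
        if w.chrom not in per:
            continue
        starts, ends = per[w.chrom]
        if mode == "overlap":
            out[i] = np.searchsorted(starts, w.end, side="left") - np.searchsorted(
                ends, w.start, side="right"
            )
        else:
            if w.chrom not in mid_cache:
                mid_cache[w.chrom] = np.sort((starts + (ends - starts) // 2))
            mids = mid_cache[w.chrom]
            out[i] = np.searchsorted(mids, w.end, side="left") - np.searchsorted(
                mids, w.start, side="left"
            )
    return out


def count_matrix(
    samples: Sequence[FragmentSet],
    windows: Sequence[GenomicInterval],
    mode: str = "overlap",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts (windows x samples), library sizes, and is-experimental mask."""
    counts = np.column_stack(
        [count_fragments(s, windows, mode=mode) for s in samples]
    ) if len(windows) else np.zeros((0, len(samples)), dtype=np.int64)
    libs = np.array([s.library_size for s in samples], dtype=np.int64)
    is_exp = np.array([s.condition == "BrdU+" for s in samples])
    return counts, libs, is_exp


# NOTE: midpoint cache in count_fragments recomputes per call; fine at the
# problem sizes used here.


# ---------------------------------------------------------------------------
# Candidate peak calling (Poisson local-lambda)
# ---------------------------------------------------------------------------

def call_candidate_peaks(
    exp_fragments: Sequence[FragmentSet],
    bg_fragments: Sequence[FragmentSet],
    genome: GenomeModel,
    bin_size: int = 50,
    q_threshold: float = 0.05,
    merge_gap: int = 200,
    min_length: int = 150,
) -> list[GenomicInterval]:
    """Fragment-pileup peak scan at ``bin_size`` resolution.

    Per-bin Poisson p-value against lambda_local = max(lambda_genome,
    lambda_5kb, lambda_10kb) estimated from the pooled background (scaled to
    the experimental depth), or from the experiment-wide rate if no
    background is given. BH-corrected bins with q <= threshold are merged
    within ``merge_gap`` bp; peaks shorter than ``min_length`` are dropped.
    """
    if not exp_fragments:
        raise ValidationError("empty experimental input")
    from .core import CoverageTrack

    def pooled_pileup(sets: Sequence[FragmentSet]) -> dict[str, np.ndarray]:
        total: dict[str, np.ndarray] = {}
        for s in sets:
            t = CoverageTrack.from_fragments(s, genome, bin_size, rpm=False)
            for c, arr in t.data.items():
                total[c] = total.get(c, 0) + arr
        return total

    exp = pooled_pileup(exp_fragments)
    exp_mass = sum(arr.sum() for arr in exp.values())
    if exp_mass == 0:
        raise ValidationError("experimental fragment sets are empty")
    n_bins_total = sum(len(a) for a in exp.values())
    if bg_fragments:
        bg = pooled_pileup(bg_fragments)
        bg_mass = sum(arr.sum() for arr in bg.values())
        scale = exp_mass / bg_mass if bg_mass > 0 else 1.0
    else:
        bg = None
        scale = 1.0

    def local_mean(arr: np.ndarray, width_bp: int) -> np.ndarray:
        k = max(1, width_bp // bin_size)
        kern = np.ones(k) / k
        return np.convolve(arr, kern, mode="same")

    lam_genome = (
        (sum(a.sum() for a in bg.values()) if bg is not None else exp_mass)
        / n_bins_total
    ) * (scale if bg is not None else 1.0)

    all_p = []
    all_bins = []  # (chrom, bin index)
    for chrom, counts in exp.items():
        if bg is not None:
            base = bg[chrom] * scale
            lam = np.maximum(
                lam_genome,
                np.maximum(local_mean(base, 5000), local_mean(base, 10000)),
            )
        else:
            lam = np.full_like(counts, lam_genome)
        p = np.clip(sps.poisson.sf(counts - 1, lam), 1e-300, 1.0)
        all_p.append(p)
        all_bins.append((chrom, len(counts)))
    pvec = np.concatenate(all_p)
    q = bh_fdr(pvec)
    peaks: list[GenomicInterval] = []
    offset = 0
    for chrom, n in all_bins:
        qc = q[offset : offset + n]
        offset += n
        sig = np.flatnonzero(qc <= q_threshold)
        if len(sig) == 0:
            continue
        ivs = [
            GenomicInterval(chrom, int(b) * bin_size, (int(b) + 1) * bin_size)
            for b in sig
        ]
        for m in merge_intervals(ivs, max_gap=merge_gap):
            if len(m) >= min_length:
                peaks.append(m)
    peaks.sort(key=lambda iv: (iv.chrom, iv.start))
    return peaks


# ---------------------------------------------------------------------------
# Differential test
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: np.ndarray,
    library_sizes: np.ndarray,
    is_exp: np.ndarray,
    min_total: int = 10,
) -> float:
    """Method-of-moments NB dispersion from within-condition replicate
    variance of count proportions (ratio-of-means across windows, so the
    estimate is stable and unaffected by between-condition differences)."""
    counts = np.asarray(counts, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    total = counts.sum(axis=1)
    use = total >= min_total
    num = 0.0
    den = 0.0
    for cond_mask in (is_exp, ~is_exp):
        if cond_mask.sum() < 2:
            continue
        k = counts[np.ix_(use, cond_mask)]
        l = libs[cond_mask]
        phat = k / l
        pbar = k.sum(axis=1) / l.sum()
        s2 = phat.var(axis=1, ddof=1)
        binom_var = pbar * (1 - pbar) * np.mean(1.0 / l)
        num += float(np.sum(s2 - binom_var))
        den += float(np.sum(pbar**2))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def differential_window_test(
    counts: np.ndarray,
    library_sizes: np.ndarray,
    is_exp: np.ndarray,
    dispersion: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-sided enrichment test per window.

    Returns (log2 fold change, one-sided p, dispersion used). Windows with
    zero total count get p = 1 and log2FC = 0. The pooled experimental count
    k of t is tested against beta-binomial(t, p0, rho) where
    p0 = sum(libE)/(sum(libE)+sum(libC)) and the beta-binomial total shape is
    (n_samples)/dispersion (exact for gamma-Poisson replicates with equal
    libraries); it reduces to binomial(t, p0) as dispersion -> 0.
    """
    counts = np.asarray(counts)
    libs = np.asarray(library_sizes, dtype=float)
    is_exp = np.asarray(is_exp, dtype=bool)
    if counts.ndim != 2 or counts.shape[1] != len(libs):
        raise ValidationError("counts must be windows x samples")
    if np.any(libs <= 0):
        raise ValidationError("library sizes must be positive")
    if is_exp.sum() < 1 or (~is_exp).sum() < 1:
        raise ValidationError("need >= 1 replicate per condition")
    if dispersion is None:
        dispersion = estimate_dispersion(counts, libs, is_exp)
    lib_e = libs[is_exp].sum()
    lib_c = libs[~is_exp].sum()
    p0 = lib_e / (lib_e + lib_c)
    k = counts[:, is_exp].sum(axis=1).astype(np.int64)
    t = k + counts[:, ~is_exp].sum(axis=1).astype(np.int64)
    pseudo = 0.5 / libs.min()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((k / lib_e + pseudo) / ((t - k) / lib_c + pseudo))
    nonzero = t > 0
    p = np.ones(len(k))
    if dispersion <= 1e-8:
        p[nonzero] = sps.binom.sf(k[nonzero] - 1, t[nonzero], p0)
    else:
        shape_total = counts.shape[1] / dispersion
        a = p0 * shape_total
        b = (1 - p0) * shape_total
        p[nonzero] = sps.betabinom.sf(k[nonzero] - 1, t[nonzero], a, b)
    log2fc[~nonzero] = 0.0
    # a one-sided tail probability is never exactly zero; guard underflow
    p = np.clip(p, 1e-300, 1.0)
    return log2fc, p, float(dispersion)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, in [0,1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# TSS sliding-window scan
# ---------------------------------------------------------------------------

def tss_window_scan(
    tss_list: Sequence[tuple[str, int]],
    samples: Sequence[FragmentSet],
    genome: GenomeModel,
    window_length: int = 1000,
    flank: int = 1000,
    step: int = 100,
    dispersion: float | None = None,
    pooled_fdr: bool = False,
    mode: str = "overlap",
) -> list[DifferentialWindow]:
    """Differential windows at offsets k = 0..K around every TSS.

    Offset set k holds, per TSS, the window [TSS - flank + k*step, ... +
    window_length); overlapping windows across TSSs within one set are merged
    before counting; each set is tested and BH-corrected independently (a
    pooled-FDR mode is available for sensitivity analysis).
    """
    n_sets = (2 * flank - window_length) // step + 1
    all_windows: list[DifferentialWindow] = []
    set_payload = []
    if dispersion is None:
        # estimate once per run from the central offset set
        k_mid = (n_sets - 1) // 2
        mid_windows = _offset_windows(
            tss_list, genome, flank, window_length, step, k_mid
        )
        counts, libs, is_exp = count_matrix(samples, mid_windows, mode=mode)
        dispersion = estimate_dispersion(counts, libs, is_exp)
    for kset in range(n_sets):
        windows = _offset_windows(
            tss_list, genome, flank, window_length, step, kset
        )
        counts, libs, is_exp = count_matrix(samples, windows, mode=mode)
        log2fc, p, _ = differential_window_test(
            counts, libs, is_exp, dispersion=dispersion
        )
        set_payload.append((f"tss_offset_{kset}", windows, counts, log2fc, p))
    if pooled_fdr:
        all_p = np.concatenate([pl[4] for pl in set_payload])
        all_q = bh_fdr(all_p)
        offset = 0
        for set_id, windows, counts, log2fc, p in set_payload:
            q = all_q[offset : offset + len(p)]
            offset += len(p)
            all_windows.extend(
                _wrap_windows(set_id, windows, counts, log2fc, p, q)
            )
    else:
        for set_id, windows, counts, log2fc, p in set_payload:
            q = bh_fdr(p)
            all_windows.extend(
                _wrap_windows(set_id, windows, counts, log2fc, p, q)
            )
    return all_windows


def _offset_windows(
    tss_list: Sequence[tuple[str, int]],
    genome: GenomeModel,
    flank: int,
    window_length: int,
    step: int,
    kset: int,
) -> list[GenomicInterval]:
    raw = []
    for chrom, pos in tss_list:
        s = pos - flank + kset * step
        e = s + window_length
        if s < 0 or e > genome.chrom_lengths[chrom]:
            continue
        raw.append(GenomicInterval(chrom, s, e))
    return merge_intervals(raw)


def _wrap_windows(set_id, windows, counts, log2fc, p, q):
    return [
        DifferentialWindow(w, counts[i], float(log2fc[i]), float(p[i]), float(q[i]), set_id)
        for i, w in enumerate(windows)
    ]


# ---------------------------------------------------------------------------
# Combine & merge
# ---------------------------------------------------------------------------

def combine_and_merge(
    windows: Sequence[DifferentialWindow],
    fdr_threshold: float = 0.05,
    max_gap: int = 0,
) -> list[TRILocus]:
    """Union of all significant members, merged; the highest member FDR is
    kept per merged locus; provenance preserved; output disjoint, sorted."""
    sig = [w for w in windows if w.fdr <= fdr_threshold]
    if not sig:
        return []
    merged = merge_intervals([w.interval for w in sig], max_gap=max_gap)
    loci = []
    for m in merged:
        members = [w for w in sig if w.interval.overlaps(m)]
        loci.append(
            TRILocus(
                interval=m,
                fdr=max(w.fdr for w in members),
                provenance=[(w.set_id, w.interval, w.fdr) for w in members],
            )
        )
    return loci


def assign_genes(
    tri_loci: Sequence[TRILocus],
    genes: Sequence[GeneAnnotation],
    samples: Sequence[FragmentSet] | None = None,
    genome: GenomeModel | None = None,
    flank: int = 1500,
    active_floor: int = 0,
    activity_flank: int = 1000,
) -> tuple[list[TRILocus], list[GeneAnnotation]]:
    """Associate genes whose TSS lies within +-flank of each locus center;
    derive the control TSS (cTSS) set: active TSSs (pooled fragment count in
    the +-1 kb TSS window above the floor) not associated with any TRI."""
    tri_gene_ids: set[str] = set()
    for locus in tri_loci:
        c = locus.interval.center
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == locus.interval.chrom and abs(g.tss - c) <= flank
        ]
        locus.genes = sorted(hits)
        tri_gene_ids.update(hits)
    if samples is not None and genome is not None:
        windows = []
        kept = []
        for g in genes:
            s = max(0, g.tss - activity_flank)
            e = min(genome.chrom_lengths[g.chrom], g.tss + activity_flank)
            windows.append(GenomicInterval(g.chrom, s, e))
            kept.append(g)
        pooled = np.zeros(len(windows), dtype=np.int64)
        for smp in samples:
            pooled += count_fragments(smp, windows)
        active = {g.gene_id for g, c in zip(kept, pooled) if c > active_floor}
    else:
        active = {g.gene_id for g in genes}
    ctss = [
        g for g in genes if g.gene_id in active and g.gene_id not in tri_gene_ids
    ]
    return list(tri_loci), ctss
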