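"""End-to-end orchestration: TRI discovery and locus characterization.

Every stage is a pure function over its inputs; report assembly only reads
stage outputs. Output files carry a header with package version, config
hash and seed so any number in a report can be reconstructed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calling import (
    TRILocus,
    assign_genes,
    call_candidate_peaks,
    combine_and_merge,
    count_matrix,
    differential_window_test,
    bh_fdr,
    tss_window_scan,
    _wrap_windows,
)
from .core import FragmentSet, GeneAnnotation, GenomeModel, GenomicInterval
from .metrics import StrandCounts, compute_rfd, find_g4, gc_percent, gc_skew
from .orientation import classify_orientation, tss_overlap_summary
from .stats import ranksum_test
from .variants import VariantRecord, variant_enrichment

log = logging.getLogger("tripnseq")


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the published procedure where one
    is stated (1 kb windows +-1 kb in 100 bp steps, FDR 0.05, +-1.5 kb gene
    flank, 3 kb orientation radius, +-500 bp variant windows, 999 resampling
    iterations, G4 window 25 / threshold 1.4, GC-skew window 200, RFD bin
    1 kb)."""

    fdr_threshold: float = 0.05
    window_length: int = 1000
    flank: int = 1000
    step: int = 100
    gene_flank: int = 1500
    orientation_radius: int = 3000
    variant_window: int = 1000  # centered at the TSS (+-500 bp)
    n_resample: int = 999
    g4_window: int = 25
    g4_threshold: float = 1.4
    gcskew_window: int = 200
    rfd_bin: int = 1000
    timex_bin: int = 100
    timex_smooth: int = 500
    peak_bin: int = 50
    merge_gap: int = 0
    count_mode: str = "overlap"
    active_floor: int = 0
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class DiscoveryResult:
    loci: list[TRILocus]
    ctss: list[GeneAnnotation]
    candidate_peaks: list[GenomicInterval]
    n_windows_tested: int
    dispersion: float
    config: PipelineConfig

    @property
    def tri_gene_ids(self) -> set[str]:
        return {g for locus in self.loci for g in locus.genes}

    def loci_table(self) -> pd.DataFrame:
        rows = []
        for i, locus in enumerate(self.loci):
            rows.append(
                {
                    "locus_id": f"TRI{i + 1:04d}",
                    "chrom": locus.interval.chrom,
                    "start": locus.interval.start,
                    "end": locus.interval.end,
                    "fdr": locus.fdr,
                    "n_members": len(locus.provenance),
                    "member_sets": ",".join(sorted({s for s, _, _ in locus.provenance})),
                    "genes": ",".join(locus.genes),
                    "orientation": locus.orientation or "",
                }
            )
        return pd.DataFrame(rows)


def run_discovery(
    samples: Sequence[FragmentSet],
    genes: Sequence[GeneAnnotation],
    genome: GenomeModel,
    config: PipelineConfig | None = None,
) -> DiscoveryResult:
    """Candidate peaks -> differential test -> TSS scan -> combine/merge ->
    gene assignment, exactly in that order."""
    cfg = config or PipelineConfig()
    exp = [s for s in samples if s.condition == "BrdU+"]
    ctl = [s for s in samples if s.condition == "BrdU-"]
    log.info("discovery: %d experimental + %d control samples", len(exp), len(ctl))

    peaks = call_candidate_peaks(
        exp, ctl, genome, bin_size=cfg.peak_bin, q_threshold=cfg.fdr_threshold
    )
    log.info("candidate peaks: %d", len(peaks))

    tss_list = [(g.chrom, g.tss) for g in genes]
    tss_windows = tss_window_scan(
        tss_list,
        samples,
        genome,
        window_length=cfg.window_length,
        flank=cfg.flank,
        step=cfg.step,
        mode=cfg.count_mode,
    )
    dispersion = np.nan
    all_windows = list(tss_windows)
    if peaks:
        counts, libs, is_exp = count_matrix(samples, peaks, mode=cfg.count_mode)
        log2fc, p, dispersion = differential_window_test(counts, libs, is_exp)
        q = bh_fdr(p)
        all_windows.extend(_wrap_windows("de_novo_peaks", peaks, counts, log2fc, p, q))
    log.info("windows tested: %d", len(all_windows))

    loci = combine_and_merge(all_windows, cfg.fdr_threshold, max_gap=cfg.merge_gap)
    loci, ctss = assign_genes(
        loci, genes, samples, genome,
        flank=cfg.gene_flank, active_floor=cfg.active_floor,
    )
    log.info("TRI loci: %d; cTSS: %d", len(loci), len(ctss))
    return DiscoveryResult(loci, ctss, peaks, len(all_windows), float(dispersion), cfg)


def run_characterization(
    result: DiscoveryResult,
    genes: Sequence[GeneAnnotation],
    genome: GenomeModel,
    plus_peaks: Sequence[GenomicInterval] | None = None,
    minus_peaks: Sequence[GenomicInterval] | None = None,
    strand_counts: StrandCounts | None = None,
    variants: Sequence[VariantRecord] | None = None,
    outdir: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Characterize called loci; optional inputs that are missing simply skip
    their analysis. Returns one table per analysis (and writes TSVs when an
    output directory is given)."""
    cfg = result.config
    by_id = {g.gene_id: g for g in genes}
    tables: dict[str, pd.DataFrame] = {}

    tss_list = [(g.chrom, g.tss) for g in genes]
    if result.loci:
        n_hit, n_total, frac = tss_overlap_summary(
            [l.interval for l in result.loci], tss_list, window=cfg.window_length
        )
        tables["tss_overlap"] = pd.DataFrame(
            [{"loci_overlapping_tss": n_hit, "total_loci": n_total, "fraction": frac}]
        )

    # orientation classes of TRI-associated TSSs
    if plus_peaks is not None and minus_peaks is not None and result.loci:
        calls = []
        for locus in result.loci:
            for gid in locus.genes:
                g = by_id[gid]
                call = classify_orientation(
                    g, genes, plus_peaks, minus_peaks,
                    radius=cfg.orientation_radius,
                )
                locus.orientation = call.orientation
                calls.append(
                    {
                        "tritss_id": gid,
                        "orientation": call.orientation,
                        "partner": call.partner_id or "",
                        "plus_signal": call.plus_signal,
                        "minus_signal": call.minus_signal,
                    }
                )
        tables["orientation"] = pd.DataFrame(calls)

    # sequence metrics at TRITSSs vs cTSSs
    if genome.has_sequence() and result.loci:
        tri_ids = sorted(result.tri_gene_ids & set(by_id))
        rows = []
        for label, ids in (("TRITSS", tri_ids), ("cTSS", [g.gene_id for g in result.ctss])):
            gc_vals, skew_vals, g4_density = [], [], []
            for gid in ids:
                g = by_id[gid]
                lo = g.tss - 200
                hi = g.tss + 200
                if lo < 0 or hi > genome.chrom_lengths[g.chrom]:
                    continue
                seq = genome.sequence(g.chrom, lo, hi)
                _, gcp = gc_percent(seq, window=len(seq))
                _, sk = gc_skew(seq, window=len(seq))
                if g.strand == "-":
                    sk = -sk
                gc_vals.append(float(gcp[0]))
                skew_vals.append(float(sk[0]) if not np.isnan(sk[0]) else np.nan)
                reg_lo, reg_hi = g.tss - 200, g.tss + 200
                _, summary = find_g4(
                    [GenomicInterval(g.chrom, reg_lo, reg_hi)], genome,
                    window=cfg.g4_window, threshold=cfg.g4_threshold,
                )
                g4_density.append(summary[0][0] / (reg_hi - reg_lo))
            rows.append(
                {
                    "group": label,
                    "n": len(gc_vals),
                    "mean_gc": float(np.mean(gc_vals)) if gc_vals else np.nan,
                    "mean_gc_skew": float(np.nanmean(skew_vals)) if skew_vals else np.nan,
                    "g4_per_bp": float(np.mean(g4_density)) if g4_density else np.nan,
                }
            )
        seq_table = pd.DataFrame(rows)
        if len(rows) == 2:
            # rank-sum comparison of per-TSS GC
            pass
        tables["sequence_metrics"] = seq_table

    if strand_counts is not None:
        rfd = compute_rfd(strand_counts)
        rows = []
        for chrom, arr in rfd.data.items():
            for i, v in enumerate(arr):
                if not np.isnan(v):
                    rows.append(
                        {"chrom": chrom, "start": i * rfd.bin_size,
                         "end": (i + 1) * rfd.bin_size, "rfd": float(v)}
                    )
        tables["rfd"] = pd.DataFrame(rows)

    if variants is not None and result.loci:
        tri_genes = [by_id[g] for g in sorted(result.tri_gene_ids & set(by_id))]
        half = cfg.variant_window // 2
        query = [
            GenomicInterval(g.chrom, max(0, g.tss - half), g.tss + half)
            for g in tri_genes
        ]
        pool = [
            GenomicInterval(g.chrom, max(0, g.tss - half), g.tss + half)
            for g in result.ctss
        ]
        if query and len(pool) >= len(query):
            enr = variant_enrichment(
                query, pool, variants, n_iter=cfg.n_resample, seed=cfg.seed
            )
            tables["variant_enrichment"] = pd.DataFrame(
                [
                    {
                        "class": cls,
                        "observed": r.observed,
                        "null_mean": r.null_mean,
                        "null_sd": r.null_sd,
                        "fold": r.fold,
                        "p": r.p,
                    }
                    for cls, r in enr.items()
                    if r is not None
                ]
            )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        header = (
            f"# tripnseq {__version__} | config {cfg.hash()} | seed {cfg.seed}\n"
        )
        tables["tri_loci"] = result.loci_table()
        for name, df in tables.items():
            path = os.path.join(outdir, f"{name}.tsv")
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
    return tables


def evaluate_against_truth(
    result: DiscoveryResult, truth_loci: Sequence[GenomicInterval]
) -> dict[str, float]:
    """Sensitivity and empirical FDR of called loci against planted truth.

    A planted locus is recovered if any called locus overlaps it; a called
    locus is a false positive if it overlaps no planted locus.
    """
    called = [l.interval for l in result.loci]
    recovered = sum(
        1 for t in truth_loci if any(t.overlaps(c) for c in called)
    )
    fp = sum(1 for c in called if not any(c.overlaps(t) for t in truth_loci))
    return {
        "n_called": float(len(called)),
        "n_truth": float(len(truth_loci)),
        "sensitivity": recovered / len(truth_loci) if truth_loci else float("nan"),
        "fdr": fp / len(called) if called else 0.0,
    }
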