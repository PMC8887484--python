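"""Metagene machinery: anchored signal matrices, median +- SE aggregation,
scaled gene-body profiles, size-matched control sampling, and region-group
comparison via the rank-sum test."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    CoverageTrack,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    ValidationError,
    map_signal_summary,
)
from .stats import ranksum_test


@dataclass
class ProfileMatrix:
    """Rows = regions, columns = bin offsets relative to the anchor."""

    region_ids: list[str]
    offsets: np.ndarray  # bp offset of each column's left edge (point mode)
    values: np.ndarray  # regions x bins, NaN-aware
    bin_size: int
    anchor_mode: str  # "point" | "scaled_body"
    strand_flip: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.region_ids):
            raise ValidationError("matrix shape mismatch")
        if self.values.shape[1] != len(self.offsets):
            raise ValidationError("offset/column mismatch")


def build_matrix(
    regions: Sequence[GenomicInterval],
    track: CoverageTrack,
    genome: GenomeModel,
    flank_up: int = 1500,
    flank_down: int = 1500,
    bin_size: int = 10,
    anchor: str = "center",
    strand_flip: bool = False,
) -> ProfileMatrix:
    """Per-region per-bin mean signal around a point anchor.

    ``anchor`` is 'center' or 'start' (for TSS-anchored point intervals use
    1 bp intervals or 'start'). Regions overlapping the blacklist or whose
    window leaves the chromosome are excluded. With ``strand_flip``,
    minus-strand rows are reversed so columns read in transcription
    direction.
    """
    if flank_up % bin_size or flank_down % bin_size:
        raise ValidationError("bin_size must divide the flanks")
    n_bins = (flank_up + flank_down) // bin_size
    offsets = np.arange(-flank_up, flank_down, bin_size)
    rows = []
    ids = []
    for region in regions:
        pos = region.center if anchor == "center" else region.start
        lo, hi = pos - flank_up, pos + flank_down
        if lo < 0 or hi > genome.chrom_lengths.get(region.chrom, -1):
            continue
        window = GenomicInterval(region.chrom, lo, hi)
        if genome.overlaps_blacklist(window):
            continue
        starts = lo + np.arange(n_bins) * bin_size
        row = track.window_means(region.chrom, starts, starts + bin_size)
        if strand_flip and region.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(region.name or f"{region.chrom}:{region.start}-{region.end}")
    values = np.vstack(rows) if rows else np.empty((0, n_bins))
    return ProfileMatrix(ids, offsets, values, bin_size, "point", strand_flip)


def aggregate(matrix: ProfileMatrix) -> dict[str, np.ndarray]:
    """Per-bin median, standard error (sd/sqrt(n)) and n over non-missing rows."""
    vals = matrix.values
    n = np.sum(~np.isnan(vals), axis=0)
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            median = np.nanmedian(vals, axis=0)
            sd = np.nanstd(vals, axis=0, ddof=0)
    se = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    median = np.where(n > 0, median, np.nan)
    return {"offset": matrix.offsets, "median": median, "se": se, "n": n}


def scaled_body_matrix(
    genes: Sequence[GeneAnnotation],
    track: CoverageTrack,
    genome: GenomeModel,
    body_bins: int = 100,
    flank: int = 10_000,
    bin_size: int = 100,
    strand_flip: bool = True,
) -> ProfileMatrix:
    """Gene bodies resampled to ``body_bins`` columns with native-binned
    flanks, read in transcription direction (flip on by default)."""
    if flank % bin_size:
        raise ValidationError("bin_size must divide the flank")
    n_flank = flank // bin_size
    rows = []
    ids = []
    for g in genes:
        if g.length < body_bins:
            continue
        lo = g.start - flank
        hi = g.end + flank
        if lo < 0 or hi > genome.chrom_lengths.get(g.chrom, -1):
            continue
        if genome.overlaps_blacklist(GenomicInterval(g.chrom, lo, hi)):
            continue
        left_starts = lo + np.arange(n_flank) * bin_size
        left = track.window_means(g.chrom, left_starts, left_starts + bin_size)
        edges = np.linspace(g.start, g.end, body_bins + 1).astype(np.int64)
        body = track.window_means(g.chrom, edges[:-1], edges[1:])
        right_starts = g.end + np.arange(n_flank) * bin_size
        right = track.window_means(g.chrom, right_starts, right_starts + bin_size)
        row = np.concatenate([left, body, right])
        if strand_flip and g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    n_cols = 2 * n_flank + body_bins
    offsets = np.arange(n_cols)  # column index; body spans [n_flank, n_flank+body_bins)
    values = np.vstack(rows) if rows else np.empty((0, n_cols))
    return ProfileMatrix(ids, offsets, values, bin_size, "scaled_body", strand_flip)


def match_sample(
    regions: Sequence, n: int, seed: int = 0
) -> list:
    """Uniform subsample without replacement (size-matched control set)."""
    if n > len(regions):
        raise ValidationError(f"cannot sample {n} from {len(regions)} regions")
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.choice(len(regions), size=n, replace=False)
    return [regions[int(i)] for i in idx]


def compare_region_groups(
    group_a: Sequence[GenomicInterval],
    group_b: Sequence[GenomicInterval],
    track: CoverageTrack,
    sub_window: int = 10,
    stat: str = "median",
) -> dict:
    """Region-summary comparison between two region groups.

    Each region is summarized by the stat (default median) of track signal
    per sub-window averaged across the region, then the two groups of
    summaries are compared with the two-sided rank-sum test.
    """
    if not len(group_a) or not len(group_b):
        raise ValidationError("both groups must be non-empty")
    a = map_signal_summary(group_a, track, sub_window, stat=stat)
    b = map_signal_summary(group_b, track, sub_window, stat=stat)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("a group has all-missing summaries")
    w, p = ranksum_test(a, b)
    return {
        "summaries_a": a,
        "summaries_b": b,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "statistic": w,
        "p_value": p,
    }
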