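"""Variant classification and region-level variant-enrichment resampling."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GenomicInterval, ValidationError, merge_intervals
from .stats import ResamplingResult

VARIANT_CLASSES = ("SBS", "insertion", "deletion", "other")


def classify_variant(ref: str, alt: str) -> str:
    """SBS if both alleles are single bases; insertion if alt extends a
    shared anchor base; deletion if ref is longer; otherwise 'other'."""
    if not ref or not alt:
        raise ValidationError("empty allele")
    if len(ref) == 1 and len(alt) == 1:
        return "SBS"
    if len(alt) > len(ref) and alt[0] == ref[0]:
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "other"


@dataclass(frozen=True)
class VariantRecord:
    """A single-allele variant; ``pos`` is 0-based (converted from VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str = field(init=False)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles are identical")
        object.__setattr__(self, "vclass", classify_variant(self.ref, self.alt))


def read_vcf(path: str, deduplicate: bool = True) -> list[VariantRecord]:
    """Read a VCF (v4.x, minimal CHROM/POS/REF/ALT); multi-allelic records
    are split into per-allele records; identical (chrom,pos,ref,alt) records
    are deduplicated by default."""
    import pysam

    out: list[VariantRecord] = []
    seen: set[tuple] = set()
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                key = (rec.chrom, rec.pos - 1, rec.ref, alt)
                if deduplicate:
                    if key in seen:
                        continue
                    seen.add(key)
                out.append(VariantRecord(rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


def write_vcf(
    records: Sequence[VariantRecord],
    path: str,
    contigs: dict[str, int] | None = None,
) -> None:
    """Minimal VCFv4.2 writer (positions converted back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")


def count_variants_in_regions(
    variants: Sequence[VariantRecord],
    regions: Sequence[GenomicInterval],
    per_kb: bool = False,
) -> dict[str, float]:
    """Total and per-class variant counts over a merged region set.

    Overlapping regions are merged first so no variant is double-counted. In
    ``per_kb`` mode each region is split into 1 kb windows and the mean
    per-window count is reported (gene-length normalization).
    """
    merged = merge_intervals(regions)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    counts = {c: 0 for c in VARIANT_CLASSES}
    total = 0
    for v in variants:
        spans = by_chrom.get(v.chrom)
        if not spans:
            continue
        # merged spans are sorted and disjoint
        import bisect

        i = bisect.bisect_right([s for s, _ in spans], v.pos) - 1
        if i >= 0 and spans[i][0] <= v.pos < spans[i][1]:
            counts[v.vclass] += 1
            total += 1
    out: dict[str, float] = {"total": float(total), **{k: float(v) for k, v in counts.items()}}
    if per_kb:
        n_windows = sum(-(-len(iv) // 1000) for iv in merged)
        if n_windows:
            out = {k: v / n_windows for k, v in out.items()}
    return out


def _region_class_counts(
    variants: Sequence[VariantRecord], regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-region per-class counts (rows follow ``regions``; regions taken
    as given, without merging)."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append((v.pos, v.vclass))
    arrays = {}
    for chrom, items in by_chrom.items():
        items.sort()
        pos = np.array([p for p, _ in items], dtype=np.int64)
        cls = np.array([VARIANT_CLASSES.index(c) for _, c in items])
        arrays[chrom] = (pos, cls)
    out = np.zeros((len(regions), len(VARIANT_CLASSES)), dtype=np.int64)
    for i, iv in enumerate(regions):
        if iv.chrom not in arrays:
            continue
        pos, cls = arrays[iv.chrom]
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        if hi > lo:
            out[i] = np.bincount(cls[lo:hi], minlength=len(VARIANT_CLASSES))
    return out


def variant_enrichment(
    query_regions: Sequence[GenomicInterval],
    control_pool: Sequence[GenomicInterval],
    variants: Sequence[VariantRecord],
    n_iter: int = 999,
    seed: int = 0,
    classes: Sequence[str] = ("SBS", "insertion", "deletion"),
) -> dict[str, ResamplingResult | None]:
    """Per-class variant enrichment of query regions over a control pool.

    Observed = class count over the query set; each null draw samples
    |query| control regions without replacement and re-counts. Classes with
    zero variants genome-wide yield None (fold undefined).
    """
    if len(query_regions) > len(control_pool):
        raise ValidationError("query set larger than the control pool")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    q_counts = _region_class_counts(variants, query_regions).sum(axis=0)
    pool_counts = _region_class_counts(variants, control_pool)
    rng = np.random.Generator(np.random.PCG64(seed))
    k = len(query_regions)
    draws = np.empty((n_iter, len(VARIANT_CLASSES)))
    for i in range(n_iter):
        idx = rng.choice(len(control_pool), size=k, replace=False)
        draws[i] = pool_counts[idx].sum(axis=0)
    out: dict[str, ResamplingResult | None] = {}
    for cls in classes:
        ci = VARIANT_CLASSES.index(cls)
        if q_counts[ci] == 0 and draws[:, ci].sum() == 0:
            out[cls] = None
            continue
        out[cls] = ResamplingResult(float(q_counts[ci]), draws[:, ci])
    return out
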