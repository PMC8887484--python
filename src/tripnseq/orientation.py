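"""Transcription-orientation classification of TRI-associated TSSs.

A focal TSS is classified against annotated TSSs and strand-specific
nascent-transcription peaks: a divergent pair has an opposite-strand
annotated TSS within the radius on its upstream side, a convergent pair on
its downstream side (both TSSs must carry own-strand signal); a single gene
with unannotated divergent transcription has no annotated neighbor but
signal on both strands; anything else is unclassified.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import GeneAnnotation, GenomicInterval, ValidationError

CLASSES = (
    "divergent_pair",
    "convergent_pair",
    "single_bidirectional",
    "unclassified",
)


@dataclass
class OrientationCall:
    tritss_id: str
    orientation: str
    partner_id: str | None = None
    plus_signal: bool = False
    minus_signal: bool = False
    candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in CLASSES:
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.orientation in ("divergent_pair", "convergent_pair"):
            if self.partner_id is None:
                raise ValidationError("paired call requires a partner id")


def _signal_at(
    chrom: str,
    pos: int,
    peaks: Sequence[GenomicInterval],
    window: int,
) -> bool:
    lo, hi = pos - window, pos + window + 1
    return any(p.chrom == chrom and p.start < hi and lo < p.end for p in peaks)


def classify_orientation(
    focal: GeneAnnotation,
    annotated: Sequence[GeneAnnotation],
    plus_peaks: Sequence[GenomicInterval],
    minus_peaks: Sequence[GenomicInterval],
    radius: int = 3000,
    signal_window: int = 500,
) -> OrientationCall:
    """Classify one TRI TSS into the four orientation classes.

    Upstream/downstream are relative to the focal TSS's own strand; partner
    distance is measured TSS-to-TSS; "signal" means >= 1 bp overlap between
    TSS +- signal_window and a strand-matched peak. When both an upstream
    and a downstream opposite-strand TSS qualify, divergent wins; all
    qualifying partners are kept in ``candidates``.
    """
    if focal.strand not in ("+", "-"):
        raise ValidationError("focal TSS requires a strand")
    if radius <= 0:
        raise ValidationError("radius must be positive")
    own = plus_peaks if focal.strand == "+" else minus_peaks
    opp = minus_peaks if focal.strand == "+" else plus_peaks
    tss = focal.tss
    own_sig = _signal_at(focal.chrom, tss, own, signal_window)
    opp_sig = _signal_at(focal.chrom, tss, opp, signal_window)
    plus_sig = own_sig if focal.strand == "+" else opp_sig
    minus_sig = opp_sig if focal.strand == "+" else own_sig

    upstream_sign = -1 if focal.strand == "+" else 1
    div_partners: list[GeneAnnotation] = []
    conv_partners: list[GeneAnnotation] = []
    any_neighbor = False
    for g in annotated:
        if g.gene_id == focal.gene_id or g.chrom != focal.chrom:
            continue
        delta = g.tss - tss
        if delta == 0 or abs(delta) > radius:
            continue
        any_neighbor = True
        if g.strand == focal.strand:
            continue
        partner_own = plus_peaks if g.strand == "+" else minus_peaks
        if not _signal_at(g.chrom, g.tss, partner_own, signal_window):
            continue
        if delta * upstream_sign > 0:
            div_partners.append(g)
        else:
            conv_partners.append(g)
    candidates = [g.gene_id for g in div_partners + conv_partners]
    if own_sig and div_partners:
        best = min(div_partners, key=lambda g: abs(g.tss - tss))
        return OrientationCall(
            focal.gene_id, "divergent_pair", best.gene_id,
            plus_sig, minus_sig, candidates,
        )
    if own_sig and conv_partners:
        best = min(conv_partners, key=lambda g: abs(g.tss - tss))
        return OrientationCall(
            focal.gene_id, "convergent_pair", best.gene_id,
            plus_sig, minus_sig, candidates,
        )
    if not any_neighbor and plus_sig and minus_sig:
        return OrientationCall(
            focal.gene_id, "single_bidirectional", None,
            plus_sig, minus_sig, candidates,
        )
    return OrientationCall(
        focal.gene_id, "unclassified", None, plus_sig, minus_sig, candidates
    )


def tss_overlap_summary(
    tri_loci: Sequence[GenomicInterval],
    tss_list: Sequence[tuple[str, int]],
    window: int = 1000,
) -> tuple[int, int, float]:
    """(loci overlapping >= 1 TSS window, total loci, fraction).

    Overlap is judged against TSS +- window/2 intervals.
    """
    if not tri_loci:
        raise ValidationError("empty locus list: fraction undefined")
    half = window // 2
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss_list:
        by_chrom.setdefault(chrom, []).append(pos)
    import numpy as np

    arrays = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}
    n_hit = 0
    for locus in tri_loci:
        pos = arrays.get(locus.chrom)
        if pos is None:
            continue
        # TSS window [pos-half, pos+half) overlaps locus iff
        # pos > locus.start - half and pos < locus.end + half
        lo = np.searchsorted(pos, locus.start - half, side="right")
        hi = np.searchsorted(pos, locus.end + half, side="left")
        if hi > lo:
            n_hit += 1
    return n_hit, len(tri_loci), n_hit / len(tri_loci)
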