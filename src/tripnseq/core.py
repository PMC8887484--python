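"""Core genomic data model and interval algebra.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; 1-based inputs (VCF positions) are converted at the parser boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when a value violates a documented invariant."""


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending line."""


STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A located span ``chrom:[start, end)`` with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeModel:
    """Ordered chromosomes with lengths, optional sequence and blacklist.

    Sequence access returns uppercase A/C/G/T/N for any in-bounds interval.
    """

    def __init__(
        self,
        chrom_lengths: dict[str, int],
        sequences: dict[str, str] | None = None,
        blacklist: Sequence[GenomicInterval] | None = None,
    ) -> None:
        for chrom, length in chrom_lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has length {length}")
        self.chrom_lengths = dict(chrom_lengths)
        self._sequences = sequences
        self._faidx = None
        self.blacklist = list(blacklist or [])
        for iv in self.blacklist:
            self._check_bounds(iv.chrom, iv.start, iv.end)

    @classmethod
    def from_fasta(
        cls, path: str, blacklist: Sequence[GenomicInterval] | None = None
    ) -> "GenomeModel":
        import pyfaidx

        fa = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)
        lengths = {name: len(fa[name]) for name in fa.keys()}
        model = cls(lengths, blacklist=blacklist)
        model._faidx = fa
        return model

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def _check_bounds(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.chrom_lengths[chrom]):
            raise ValidationError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {self.chrom_lengths[chrom]})"
            )

    def has_sequence(self) -> bool:
        return self._sequences is not None or self._faidx is not None

    def sequence(self, chrom: str, start: int, end: int) -> str:
        self._check_bounds(chrom, start, end)
        if self._sequences is not None:
            return self._sequences[chrom][start:end].upper()
        if self._faidx is not None:
            return str(self._faidx[chrom][start:end])
        raise ValidationError("genome model has no sequence accessor")

    def validate(self, iv: GenomicInterval) -> None:
        self._check_bounds(iv.chrom, iv.start, iv.end)

    def overlaps_blacklist(self, iv: GenomicInterval) -> bool:
        return any(iv.overlaps(b) for b in self.blacklist)


@dataclass
class GeneAnnotation:
    """Gene stored as interval + strand; TSS/TTS derived from strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be +/-")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: invalid interval")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, self.strand, self.gene_id
        )


class FragmentSet:
    """Per-sample collection of sequenced fragments, held as numpy arrays.

    ``chroms``/``starts``/``ends`` are parallel arrays; fragments, not reads,
    are the unit (paired-end fragment intervals). ``library_size`` equals the
    number of fragments by construction.
    """

    def __init__(
        self,
        sample_id: str,
        condition: str,
        replicate: int,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        strands: np.ndarray | None = None,
    ) -> None:
        if condition not in ("BrdU+", "BrdU-"):
            raise ValidationError(f"condition must be BrdU+ or BrdU-, got {condition!r}")
        self.sample_id = sample_id
        self.condition = condition
        self.replicate = int(replicate)
        self.chroms = np.asarray(chroms)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.strands = strands
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValidationError("fragment arrays must be parallel")
        if np.any(self.starts >= self.ends):
            raise ValidationError("fragment with start >= end")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def library_size(self) -> int:
        return len(self.starts)

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted starts, sorted ends) for interval counting."""
        if self._by_chrom is None:
            out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            order = np.argsort(self.chroms, kind="stable")
            ch = self.chroms[order]
            st = self.starts[order]
            en = self.ends[order]
            bounds = np.flatnonzero(np.r_[True, ch[1:] != ch[:-1], True])
            for i, j in zip(bounds[:-1], bounds[1:]):
                out[str(ch[i])] = (np.sort(st[i:j]), np.sort(en[i:j]))
            self._by_chrom = out
        return self._by_chrom

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(self.chroms, self.starts, self.ends)
        ]

    def validate(self, genome: GenomeModel) -> None:
        for chrom in np.unique(self.chroms):
            if str(chrom) not in genome.chrom_lengths:
                raise ValidationError(f"fragments on unknown chromosome {chrom!r}")
            mask = self.chroms == chrom
            length = genome.chrom_lengths[str(chrom)]
            if self.starts[mask].min(initial=0) < 0 or self.ends[mask].max(initial=0) > length:
                raise ValidationError(f"fragment outside {chrom} bounds")


class CoverageTrack:
    """Binned per-chromosome signal. NaN marks zero-information bins."""

    def __init__(
        self,
        bin_size: int,
        data: dict[str, np.ndarray],
        normalization: str = "raw",
    ) -> None:
        if bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        if normalization not in ("raw", "RPM"):
            raise ValidationError("normalization must be raw or RPM")
        self.bin_size = int(bin_size)
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        self.normalization = normalization

    @classmethod
    def zeros(cls, genome: GenomeModel, bin_size: int, **kw) -> "CoverageTrack":
        data = {
            c: np.zeros(math.ceil(n / bin_size))
            for c, n in genome.chrom_lengths.items()
        }
        return cls(bin_size, data, **kw)

    @classmethod
    def from_fragments(
        cls,
        fragments: FragmentSet,
        genome: GenomeModel,
        bin_size: int,
        rpm: bool = True,
    ) -> "CoverageTrack":
        """Fragment-pileup track: per bin, count of fragments overlapping it."""
        data = {}
        per = fragments.per_chrom()
        for chrom, length in genome.chrom_lengths.items():
            nbins = math.ceil(length / bin_size)
            if chrom in per:
                starts, ends = per[chrom]
                b0 = np.clip(starts // bin_size, 0, nbins - 1)
                b1 = np.clip((ends - 1) // bin_size, 0, nbins - 1)
                delta = np.bincount(b0, minlength=nbins + 1).astype(float)
                delta -= np.bincount(b1 + 1, minlength=nbins + 2)[: nbins + 1]
                data[chrom] = np.cumsum(delta[:-1])
            else:
                data[chrom] = np.zeros(nbins)
        track = cls(bin_size, data, normalization="raw")
        if rpm:
            return track.to_rpm(fragments.library_size)
        return track

    def to_rpm(self, library_size: int) -> "CoverageTrack":
        if library_size <= 0:
            raise ValidationError("library_size must be positive")
        data = {c: v * 1e6 / library_size for c, v in self.data.items()}
        return CoverageTrack(self.bin_size, data, normalization="RPM")

    def values_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Bin values overlapping [start, end)."""
        arr = self.data[chrom]
        lo = max(0, start // self.bin_size)
        hi = min(len(arr), math.ceil(end / self.bin_size))
        return arr[lo:hi]

    def mask_blacklist(self, genome: GenomeModel) -> None:
        for iv in genome.blacklist:
            if iv.chrom in self.data:
                lo = iv.start // self.bin_size
                hi = math.ceil(iv.end / self.bin_size)
                self.data[iv.chrom][lo:hi] = np.nan

    def window_means(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Base-weighted NaN-aware mean of track values over many windows."""
        arr = self.data[chrom]
        b = self.bin_size
        vals = np.nan_to_num(arr, nan=0.0)
        ok = (~np.isnan(arr)).astype(float)
        cs_val = np.concatenate([[0.0], np.cumsum(vals * b)])
        cs_cov = np.concatenate([[0.0], np.cumsum(ok * b)])
        n = len(arr)

        def prefix(cs, per_bin, x):
            x = np.clip(x, 0, n * b)
            idx = x // b
            frac = x - idx * b
            return cs[idx] + per_bin[np.minimum(idx, n - 1)] * frac * (idx < n)

        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        sums = prefix(cs_val, vals, ends) - prefix(cs_val, vals, starts)
        cov = prefix(cs_cov, ok, ends) - prefix(cs_cov, ok, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sums / cov
        out[cov == 0] = np.nan
        return out


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    items: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals within ``max_gap`` bp into disjoint sorted intervals.

    Bookended intervals (end == next start) merge at max_gap 0. Idempotent and
    order-independent; union of bases is preserved.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    items = sorted(items, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in items:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + max_gap:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``a`` not covered by ``b`` (both merged internally)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        cur = iv.start
        for cut in by_chrom.get(iv.chrom, []):
            if cut.end <= cur or cut.start >= iv.end:
                continue
            if cut.start > cur:
                out.append(GenomicInterval(iv.chrom, cur, cut.start))
            cur = max(cur, cut.end)
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end))
    return out


def intersect_count(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Per-query (number of subjects hit, total bp overlapped)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in subject:
        by_chrom.setdefault(s.chrom, []).append(s)
    arrays = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        arrays[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    out = []
    for q in query:
        if q.chrom not in arrays:
            out.append((0, 0))
            continue
        starts, ends = arrays[q.chrom]
        cand = np.flatnonzero((starts < q.end) & (ends > q.start))
        bp = int(
            np.sum(
                np.minimum(ends[cand], q.end) - np.maximum(starts[cand], q.start)
            )
        )
        out.append((len(cand), bp))
    return out


def make_windows(
    chrom: str,
    anchor: int,
    strand: str,
    flank_up: int,
    flank_down: int,
    length: int,
    step: int,
    genome: GenomeModel | None = None,
) -> list[GenomicInterval]:
    """Sliding windows of fixed ``length`` covering anchor-flank_up..anchor+flank_down.

    Flanks are strand-aware (upstream of a minus-strand anchor lies to the
    right). Windows clipped below full length at chromosome edges are dropped
    so all windows in a set are length-matched.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    if length > flank_up + flank_down:
        raise ValidationError("length must be <= flank_up + flank_down")
    if strand == "-":
        flank_up, flank_down = flank_down, flank_up
    if genome is not None:
        if chrom not in genome.chrom_lengths:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not (0 <= anchor < genome.chrom_lengths[chrom]):
            raise ValidationError(f"anchor {anchor} off chromosome {chrom}")
    first = anchor - flank_up
    last = anchor + flank_down - length
    out = []
    chrom_len = genome.chrom_lengths[chrom] if genome is not None else None
    for s in range(first, last + 1, step):
        e = s + length
        if s < 0 or (chrom_len is not None and e > chrom_len):
            continue
        out.append(GenomicInterval(chrom, s, e))
    return out


def map_signal_summary(
    regions: Sequence[GenomicInterval],
    track: CoverageTrack,
    sub_window: int,
    stat: str = "median",
) -> np.ndarray:
    """Per-region summary: stat per sub-window, then mean across sub-windows.

    Empty sub-windows (no informative track bins) are excluded from the mean;
    a region with zero covered sub-windows yields NaN.
    """
    if stat not in ("median", "mean"):
        raise ValidationError("stat must be median or mean")
    fn = np.nanmedian if stat == "median" else np.nanmean
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        if region.chrom not in track.data:
            out[i] = np.nan
            continue
        subs = []
        for s in range(region.start, region.end, sub_window):
            e = min(s + sub_window, region.end)
            vals = track.values_in(region.chrom, s, e)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                subs.append(fn(vals))
        out[i] = np.mean(subs) if subs else np.nan
    return out
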