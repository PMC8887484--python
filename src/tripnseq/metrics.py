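"""Per-base / per-bin genomic statistics.

RFD (replication fork directionality), TimEX-style replication-timing log2
ratio, GC skew, GC percent, and G-quadruplex propensity scoring with a
run-length-based per-base rule and windowed mean.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CoverageTrack, GenomeModel, GenomicInterval, ValidationError


@dataclass
class StrandCounts:
    """Per-bin forward (F) and reverse (R) strand fragment counts."""

    bin_size: int
    forward: dict[str, np.ndarray]
    reverse: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for d in (self.forward, self.reverse):
            for arr in d.values():
                if np.any(np.asarray(arr) < 0):
                    raise ValidationError("strand counts must be >= 0")


@dataclass(frozen=True)
class G4Hit:
    """Merged run of qualifying G4 windows; score sign encodes the strand."""

    interval: GenomicInterval
    score: float


def compute_rfd(counts: StrandCounts) -> CoverageTrack:
    """RFD = (R - F)/(R + F) per bin; bins with no fragments are NaN.

    +1 means purely rightward-moving forks (reverse-strand Okazaki
    fragments), -1 purely leftward. Values are bounded in [-1, 1] and the
    statistic is antisymmetric under swapping F and R.
    """
    data = {}
    for chrom in counts.forward:
        F = np.asarray(counts.forward[chrom], dtype=float)
        R = np.asarray(counts.reverse[chrom], dtype=float)
        if np.any(F < 0) or np.any(R < 0):
            raise ValidationError("negative strand counts")
        tot = F + R
        with np.errstate(invalid="ignore", divide="ignore"):
            rfd = (R - F) / tot
        rfd[tot == 0] = np.nan
        data[chrom] = rfd
    return CoverageTrack(counts.bin_size, data)


def timex_log2(
    s_phase: CoverageTrack,
    g0: CoverageTrack,
    pseudocount: float = 0.1,
    smooth: int = 500,
) -> CoverageTrack:
    """Replication-timing estimate: smoothed log2((S + c)/(G0 + c)).

    Both tracks must share the same binning (RPM scale expected). The ratio
    is smoothed with a centered running mean over ``smooth / bin_size`` bins,
    ignoring NaN (blacklisted) bins, which stay NaN.
    """
    if s_phase.bin_size != g0.bin_size:
        raise ValidationError("tracks must share bin size")
    k = max(1, int(round(smooth / s_phase.bin_size)))
    data = {}
    for chrom in s_phase.data:
        S = s_phase.data[chrom]
        G = g0.data[chrom]
        if len(S) != len(G):
            raise ValidationError(f"track lengths differ on {chrom}")
        with np.errstate(invalid="ignore"):
            ratio = np.log2((S + pseudocount) / (G + pseudocount))
        data[chrom] = _nan_running_mean(ratio, k)
    return CoverageTrack(s_phase.bin_size, data)


def _nan_running_mean(x: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean of width k, NaN-aware; NaN inputs stay NaN."""
    if k <= 1:
        return x.copy()
    nanmask = np.isnan(x)
    vals = np.where(nanmask, 0.0, x)
    ones = (~nanmask).astype(float)
    kern = np.ones(k)
    num = np.convolve(vals, kern, mode="same")
    den = np.convolve(ones, kern, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[nanmask] = np.nan
    return out


def _base_counts(seq: str) -> dict[str, np.ndarray]:
    a = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return {b: (a == b.encode()).astype(np.int64) for b in "ACGT"}


def _window_sums(indicator: np.ndarray, window: int) -> np.ndarray:
    cs = np.concatenate([[0], np.cumsum(indicator)])
    return cs[window:] - cs[:-window]


def gc_skew(
    seq: str, window: int = 200, step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding (G - C)/(G + C); value assigned to the window center.

    Returns (positions, skew) where position = start + window//2 of each
    window; windows without any G or C yield NaN. Reverse-complementing the
    sequence negates (and reverses) the profile.
    """
    seq = seq.upper()
    if window > len(seq):
        return np.array([], dtype=int), np.array([])
    c = _base_counts(seq)
    G = _window_sums(c["G"], window)[::step].astype(float)
    C = _window_sums(c["C"], window)[::step].astype(float)
    tot = G + C
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = (G - C) / tot
    skew[tot == 0] = np.nan
    pos = np.arange(0, len(seq) - window + 1, step) + window // 2
    return pos, skew


def gc_percent(
    seq: str, window: int = 200, step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding (G + C)/(A + C + G + T); N bases excluded from the denominator."""
    seq = seq.upper()
    if window > len(seq):
        return np.array([], dtype=int), np.array([])
    c = _base_counts(seq)
    gc = (_window_sums(c["G"], window) + _window_sums(c["C"], window))[::step]
    acgt = sum(_window_sums(c[b], window) for b in "ACGT")[::step].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = gc / acgt
    frac[acgt == 0] = np.nan
    pos = np.arange(0, len(seq) - window + 1, step) + window // 2
    return pos, frac


def g4_base_scores(seq: str) -> np.ndarray:
    """Per-base G4 propensity: +min(L,4) for a G in a maximal G-run of length
    L, -min(L,4) for a C in a C-run, 0 for A/T/N."""
    a = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    n = len(a)
    if n == 0:
        return np.array([])
    # code: +1 for G, -1 for C, 0 otherwise; run-length encode
    code = np.zeros(n, dtype=np.int8)
    code[a == b"G"] = 1
    code[a == b"C"] = -1
    change = np.flatnonzero(np.r_[True, code[1:] != code[:-1], True])
    scores = np.zeros(n)
    for i, j in zip(change[:-1], change[1:]):
        if code[i] != 0:
            scores[i:j] = code[i] * min(j - i, 4)
    return scores


def g4hunter_score(seq: str, window: int = 25) -> np.ndarray:
    """Arithmetic mean of per-base G4 scores over each length-``window``
    substring; bounded in [-4, 4]; negated by sequence complementation."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    scores = g4_base_scores(seq)
    if len(scores) < window:
        return np.array([])
    cs = np.concatenate([[0.0], np.cumsum(scores)])
    return (cs[window:] - cs[:-window]) / window


def find_g4(
    regions: Sequence[GenomicInterval],
    genome: GenomeModel,
    window: int = 25,
    threshold: float = 1.4,
    merge: bool = True,
) -> tuple[list[G4Hit], dict[int, tuple[int, float]]]:
    """Scan regions for G4-prone windows (|windowed score| >= threshold).

    Runs of consecutive qualifying window starts are merged into one hit
    spanning their union; hit score is the extremal window mean. Returns the
    hit list and, per region index, (hit count, hits per bp density). With
    ``merge=False`` every qualifying window is its own hit.
    """
    hits: list[G4Hit] = []
    summary: dict[int, tuple[int, float]] = {}
    for ridx, region in enumerate(regions):
        seq = genome.sequence(region.chrom, region.start, region.end)
        means = g4hunter_score(seq, window)
        qual = np.abs(means) >= threshold
        region_hits = 0
        if qual.any():
            idx = np.flatnonzero(qual)
            if merge:
                breaks = np.flatnonzero(np.diff(idx) > 1)
                groups = np.split(idx, breaks + 1)
            else:
                groups = [np.array([i]) for i in idx]
            for g in groups:
                vals = means[g]
                extremal = vals[np.argmax(np.abs(vals))]
                hits.append(
                    G4Hit(
                        GenomicInterval(
                            region.chrom,
                            region.start + int(g[0]),
                            region.start + int(g[-1]) + window,
                        ),
                        float(extremal),
                    )
                )
                region_hits += 1
        summary[ridx] = (region_hits, region_hits / len(region))
    return hits, summary


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
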