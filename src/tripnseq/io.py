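"""Standard-format I/O: BED3/BED6, bedGraph (4-column), FASTA, gene tables.

All writers emit coordinates sorted as given; round-trips are exact for
coordinates and names and exact to printed precision for scores.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import (
    CoverageTrack,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    ParseError,
    ValidationError,
)


def _parse_int(tok: str, lineno: int, path: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: expected integer, got {tok!r}") from None


def read_intervals(path: str, format: str = "BED") -> list[GenomicInterval]:
    """Read BED3/BED6 or 4-column bedGraph into intervals (file order kept)."""
    if format not in ("BED", "bedGraph"):
        raise ValidationError(f"unsupported format {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            start = _parse_int(fields[1], lineno, path)
            end = _parse_int(fields[2], lineno, path)
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid coordinates {start}-{end}"
                )
            if format == "bedGraph":
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
                try:
                    score = float(fields[3])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: bad bedGraph value {fields[3]!r}"
                    ) from None
                out.append(GenomicInterval(chrom, start, end, score=score))
            else:
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = None
                if len(fields) > 4 and fields[4] != ".":
                    try:
                        score = float(fields[4])
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: bad score {fields[4]!r}"
                        ) from None
                strand = fields[5] if len(fields) > 5 else "."
                if strand not in ("+", "-", "."):
                    raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def _fmt_score(score: float) -> str:
    if score == int(score) and abs(score) < 1e15:
        return str(int(score))
    return repr(float(score))


def write_intervals(
    items: Sequence[GenomicInterval], path: str, format: str = "BED"
) -> None:
    """Write BED6, bedGraph, or a headered TSV report."""
    if format not in ("BED", "bedGraph", "TSV"):
        raise ValidationError(f"unsupported format {format!r}")
    with open(path, "w") as fh:
        if format == "TSV":
            fh.write("chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in items:
            if format == "bedGraph":
                if iv.score is None:
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} has no score "
                        "(required for bedGraph)"
                    )
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt_score(iv.score)}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = _fmt_score(iv.score) if iv.score is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_genes(path: str) -> list[GeneAnnotation]:
    """Genes from BED6 (name = gene id; optional 7th column = biotype)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: gene BED needs 6 columns")
            biotype = f[6] if len(f) > 6 else "protein_coding"
            out.append(
                GeneAnnotation(
                    f[3], f[0], _parse_int(f[1], lineno, path),
                    _parse_int(f[2], lineno, path), f[5], biotype,
                )
            )
    return out


def write_genes(genes: Sequence[GeneAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\t{g.biotype}\n"
            )


def write_fasta(sequences: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def track_to_intervals(track: CoverageTrack) -> list[GenomicInterval]:
    """Run-length-compressed scored intervals from a track (NaN bins skipped)."""
    out = []
    b = track.bin_size
    for chrom, arr in track.data.items():
        i = 0
        n = len(arr)
        while i < n:
            if np.isnan(arr[i]):
                i += 1
                continue
            j = i + 1
            while j < n and not np.isnan(arr[j]) and arr[j] == arr[i]:
                j += 1
            out.append(GenomicInterval(chrom, i * b, j * b, score=float(arr[i])))
            i = j
    return out


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    write_intervals(track_to_intervals(track), path, format="bedGraph")


def read_bedgraph(
    path: str, genome: GenomeModel, bin_size: int
) -> CoverageTrack:
    """Rasterize a bedGraph onto a fixed binning (base-weighted bin means)."""
    return intervals_to_track(read_intervals(path, "bedGraph"), genome, bin_size)


def intervals_to_track(
    items: Iterable[GenomicInterval], genome: GenomeModel, bin_size: int
) -> CoverageTrack:
    """Scored intervals -> binned track; uncovered bins are NaN."""
    sums = {
        c: np.zeros(-(-n // bin_size)) for c, n in genome.chrom_lengths.items()
    }
    cov = {c: np.zeros_like(v) for c, v in sums.items()}
    for iv in items:
        if iv.score is None:
            raise ValidationError("intervals_to_track requires scored intervals")
        if iv.chrom not in sums:
            continue
        arr, cv = sums[iv.chrom], cov[iv.chrom]
        b0 = iv.start // bin_size
        b1 = -(-iv.end // bin_size)
        for b in range(b0, min(b1, len(arr))):
            lo = max(iv.start, b * bin_size)
            hi = min(iv.end, (b + 1) * bin_size)
            arr[b] += iv.score * (hi - lo)
            cv[b] += hi - lo
    data = {}
    for c in sums:
        with np.errstate(invalid="ignore", divide="ignore"):
            v = sums[c] / cov[c]
        v[cov[c] == 0] = np.nan
        data[c] = v
    return CoverageTrack(bin_size, data)
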