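"""Resampling and enrichment inference.

Empirical P-values of the form P = (r + 1)/(n + 1), gene-list resampling
nulls, workspace-restricted interval-overlap randomization, hypergeometric
enrichment, and the Wilcoxon rank-sum comparison (exact for small samples,
tie-corrected normal approximation with continuity correction otherwise).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import GenomicInterval, ValidationError, merge_intervals


@dataclass
class ResamplingResult:
    """Observed statistic vs a resampling null.

    ``p`` follows P = (r + 1)/(n + 1) where r counts null draws at least as
    extreme as the observation (ties count as extreme, so P > 0 always).
    ``fold`` is observed / mean(null); NaN when the null mean is zero.
    """

    observed: float
    null: np.ndarray
    direction: str = "greater"
    n: int = field(init=False)
    r: int = field(init=False)
    p: float = field(init=False)
    fold: float = field(init=False)

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=float)
        self.n = len(self.null)
        if self.n < 1:
            raise ValidationError("empty null set")
        if self.direction == "greater":
            self.r = int(np.sum(self.null >= self.observed))
        elif self.direction == "less":
            self.r = int(np.sum(self.null <= self.observed))
        else:
            raise ValidationError("direction must be 'greater' or 'less'")
        self.p = (self.r + 1) / (self.n + 1)
        m = self.null.mean()
        self.fold = self.observed / m if m > 0 else float("nan")

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null.std(ddof=1)) if self.n > 1 else 0.0

    @property
    def fold_median(self) -> float:
        m = float(np.median(self.null))
        return self.observed / m if m > 0 else float("nan")


def empirical_pvalue(
    observed: float, null_draws: Sequence[float], direction: str = "greater"
) -> ResamplingResult:
    """Empirical P = (r + 1)/(n + 1) against explicit null draws."""
    return ResamplingResult(float(observed), np.asarray(null_draws), direction)


def resample_gene_overlap(
    query_genes: Sequence[str],
    gene_universe: Sequence[str],
    target_gene_set: Sequence[str],
    n_iter: int = 999,
    seed: int = 0,
) -> ResamplingResult:
    """Overlap of a gene list with a target set vs random same-size lists.

    Each null draw samples |query| genes from the universe without
    replacement and counts the intersection with the target set.
    """
    universe = np.asarray(sorted(set(gene_universe)))
    query = set(query_genes)
    if not query <= set(universe):
        raise ValidationError("query genes must be a subset of the universe")
    if len(query) > len(universe):
        raise ValidationError("query larger than universe")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    target = set(target_gene_set)
    observed = len(query & target)
    rng = np.random.Generator(np.random.PCG64(seed))
    is_target = np.isin(universe, sorted(target))
    k = len(query)
    null = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(len(universe), size=k, replace=False)
        null[i] = is_target[idx].sum()
    return ResamplingResult(float(observed), null)


def _flatten_workspace(
    workspace: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], np.ndarray]:
    ws = merge_intervals(workspace)
    offsets = np.concatenate([[0], np.cumsum([len(w) for w in ws])])
    return ws, offsets


def _to_concat(
    items: Sequence[GenomicInterval],
    ws: Sequence[GenomicInterval],
    offsets: np.ndarray,
) -> list[tuple[int, int]]:
    """Clip items to the workspace and map them into concatenated coordinates."""
    out = []
    for iv in items:
        for j, w in enumerate(ws):
            if w.chrom != iv.chrom:
                continue
            lo = max(iv.start, w.start)
            hi = min(iv.end, w.end)
            if lo < hi:
                base = offsets[j] - w.start
                out.append((lo + base, hi + base))
    return out


def _overlap_stat(
    q: np.ndarray, ann_starts: np.ndarray, ann_ends: np.ndarray, statistic: str
) -> float:
    """Overlap of query segments (concat coords, n x 2) with merged annotations."""
    if len(ann_starts) == 0 or len(q) == 0:
        return 0.0
    s, e = q[:, 0], q[:, 1]
    # annotations are disjoint and sorted: overlap bp of [s,e) is the total
    # annotation bp between the first and last overlapped annotation, minus
    # the clipped ends of the boundary annotations
    cs = np.concatenate([[0], np.cumsum(ann_ends - ann_starts)])
    i0 = np.searchsorted(ann_ends, s, side="right")
    i1 = np.searchsorted(ann_starts, e, side="left")
    hit = i0 < i1
    bp = np.zeros(len(q), dtype=np.int64)
    if hit.any():
        lo = i0[hit]
        hi = i1[hit]
        total = cs[hi] - cs[lo]
        left_trim = np.maximum(0, s[hit] - ann_starts[lo])
        right_trim = np.maximum(0, ann_ends[hi - 1] - e[hit])
        bp[hit] = total - left_trim - right_trim
    if statistic == "bp":
        return float(bp.sum())
    return float(np.sum(bp > 0))


def workspace_overlap_test(
    query: Sequence[GenomicInterval],
    annotations: Sequence[GenomicInterval],
    workspace: Sequence[GenomicInterval],
    statistic: str = "bp",
    n_samples: int = 999,
    seed: int = 0,
) -> ResamplingResult:
    """Interval-overlap randomization restricted to a workspace.

    The workspace is flattened (merged); both query and annotations are
    clipped into it. Each null sample re-places every query segment, length
    preserved and unsplit, uniformly at random within the concatenated
    workspace (placed segments may overlap one another) and recomputes the
    overlap statistic ('bp' or 'segment_count').
    """
    if statistic not in ("bp", "segment_count"):
        raise ValidationError("statistic must be 'bp' or 'segment_count'")
    ws, offsets = _flatten_workspace(workspace)
    total = int(offsets[-1])
    if total == 0:
        raise ValidationError("empty workspace")
    for k, iv in enumerate(query):
        if len(iv) > total:
            raise ValidationError(
                f"query segment #{k} ({iv.chrom}:{iv.start}-{iv.end}, length "
                f"{len(iv)}) exceeds the workspace (total {total} bp) under "
                "non-splitting placement"
            )
    q = _to_concat(query, ws, offsets)
    if not q:
        raise ValidationError("query does not intersect the workspace")
    ann = _to_concat(annotations, ws, offsets)
    # annotations are disjoint in concat space after merging
    ann.sort()
    merged: list[list[int]] = []
    for s, e in ann:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    ann_starts = np.array([m[0] for m in merged], dtype=np.int64)
    ann_ends = np.array([m[1] for m in merged], dtype=np.int64)

    qarr = np.asarray(q, dtype=np.int64)
    lengths = qarr[:, 1] - qarr[:, 0]
    too_long = np.flatnonzero(lengths > total)
    if len(too_long):
        k = int(too_long[0])
        raise ValidationError(
            f"query segment #{k} (length {int(lengths[k])}) exceeds the "
            f"workspace (total {total} bp) under non-splitting placement"
        )
    observed = _overlap_stat(qarr, ann_starts, ann_ends, statistic)
    rng = np.random.Generator(np.random.PCG64(seed))
    null = np.empty(n_samples)
    span = total - lengths  # inclusive upper bound of start offsets
    for i in range(n_samples):
        starts = (rng.random(len(lengths)) * (span + 1)).astype(np.int64)
        placed = np.column_stack([starts, starts + lengths])
        null[i] = _overlap_stat(placed, ann_starts, ann_ends, statistic)
    return ResamplingResult(observed, null)


def hypergeometric_enrichment(
    k: int, n: int, K: int, N: int, direction: str = "greater"
) -> float:
    """Hypergeometric tail P for k successes in a sample of n, given K of N.

    'greater' sums P(X >= k) (over-representation); 'less' sums the lower
    tail P(X <= k) (depletion).
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k} n={n} K={K} N={N}"
        )
    if direction == "greater":
        return float(sps.hypergeom.sf(k - 1, N, K, n))
    if direction == "less":
        return float(sps.hypergeom.cdf(k, N, K, n))
    raise ValidationError("direction must be 'greater' or 'less'")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def ranksum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 16
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic, P).

    For pooled sample size <= ``exact_max_n`` the permutation distribution of
    the rank sum (midranks for ties) is enumerated exactly; otherwise a
    normal approximation with tie-corrected variance and continuity
    correction is used. Identical pooled samples give P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(x) + len(y)
    ranks = _midranks(pooled)
    w = float(ranks[:nx].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    if n <= exact_max_n:
        mu = nx * (n + 1) / 2.0
        dev = abs(w - mu)
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), nx):
            total += 1
            if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-9:
                count += 1
        return w, count / total
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w, float(res.pvalue)
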