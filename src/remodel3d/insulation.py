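"""Insulation scores, TAD boundary calling and differential boundaries.

The insulation score at a bin is the mean balanced contact count in the
square window spanning ``w`` bins upstream by ``w`` bins downstream of the
bin; boundaries are strict local minima of the track below a cutoff, and
TADs are the intervals between consecutive boundaries. Replicate
reconciliation merges boundaries that fall within one bin of each other
and labels condition-specific boundaries across treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BalancedMatrix

__all__ = [
    "InsulationTrack",
    "Boundary",
    "insulation_track",
    "call_boundaries_and_tads",
    "merge_replicate_boundaries",
    "reconcile_boundaries",
]


@dataclass
class InsulationTrack:
    chrom: str
    bin_size: int
    window_bp: int
    window_bins: int
    values: np.ndarray  # NaN where undefined


@dataclass
class Boundary:
    bin: int
    insulation: float
    prominence: float
    support: int = 1


def insulation_track(
    bm: BalancedMatrix,
    window_bp: int = 102_353,
    max_masked_frac: float = 0.5,
) -> InsulationTrack:
    """Mean balanced contact in the w x w square sliding along the diagonal.

    ``w = round(window_bp / bin_size)`` bins. A bin is NA when its window
    overlaps a chromosome end or when more than ``max_masked_frac`` of the
    square's cells touch masked bins.
    """
    w = int(round(window_bp / bm.bin_size))
    if w < 1:
        raise ValueError(f"window {window_bp} bp is smaller than one {bm.bin_size} bp bin")
    n = bm.n_bins
    values = np.full(n, np.nan)
    cell_ok = np.outer(bm.mask, bm.mask)
    for i in range(w, n - w):
        rows = slice(i - w, i)
        cols = slice(i + 1, i + w + 1)
        ok = cell_ok[rows, cols]
        if ok.mean() < (1.0 - max_masked_frac) or not ok.any():
            continue
        values[i] = bm.balanced[rows, cols][ok].mean()
    return InsulationTrack(
        chrom=bm.chrom, bin_size=bm.bin_size, window_bp=window_bp, window_bins=w, values=values
    )


def _local_minima(values: np.ndarray) -> list[int]:
    """Strict local minima; a flat minimum reports its leftmost bin."""
    minima = []
    n = len(values)
    i = 1
    while i < n - 1:
        if not np.isfinite(values[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and np.isfinite(values[j + 1]) and values[j + 1] == values[i]:
            j += 1
        left_ok = np.isfinite(values[i - 1]) and values[i - 1] > values[i]
        right_ok = j + 1 < n and np.isfinite(values[j + 1]) and values[j + 1] > values[i]
        if left_ok and right_ok:
            minima.append(i)
        i = j + 1
    return minima


def _prominence(values: np.ndarray, b: int) -> float:
    def flank_max(step: int) -> float:
        # walk outward until the track drops back below the minimum's level
        best = values[b]
        i = b + step
        while 0 <= i < len(values) and np.isfinite(values[i]) and values[i] >= values[b]:
            best = max(best, values[i])
            i += step
        return best

    return float(min(flank_max(-1), flank_max(+1)) - values[b])


def call_boundaries_and_tads(
    track: InsulationTrack,
    cutoff: float = 50.0,
    min_separation: int | None = None,
) -> tuple[list[Boundary], pd.DataFrame]:
    """Boundaries = strict local minima below ``cutoff`` with prominence > 0.

    A boundary depresses the insulation track over a valley about one
    window wide, which can hold several noise-level minima; minima closer
    than ``min_separation`` bins (default: the window width) are therefore
    merged, keeping the deepest (leftmost on ties). TADs are the spans
    between consecutive boundaries within each contiguous analyzable
    (non-NA) segment, including the segment ends. Returns the boundary
    list and a TAD table (chrom, start, end, size_bp).
    """
    if min_separation is None:
        min_separation = track.window_bins
    values = track.values
    candidates = [
        Boundary(bin=b, insulation=float(values[b]), prominence=_prominence(values, b))
        for b in _local_minima(values)
        if values[b] < cutoff and _prominence(values, b) > 0
    ]
    def center_of_valley(b: Boundary) -> Boundary:
        # the attenuated valley has a noisy plateau floor; report its centre
        # (bins within half the prominence of the minimum) as the boundary
        level = b.insulation + 0.5 * b.prominence
        lo = hi = b.bin
        while lo - 1 >= 0 and np.isfinite(values[lo - 1]) and values[lo - 1] < level and b.bin - lo < min_separation:
            lo -= 1
        while hi + 1 < len(values) and np.isfinite(values[hi + 1]) and values[hi + 1] < level and hi - b.bin < min_separation:
            hi += 1
        return Boundary(bin=(lo + hi) // 2, insulation=b.insulation, prominence=b.prominence)

    boundaries: list[Boundary] = []
    cluster: list[Boundary] = []
    for cand in candidates:
        if cluster and cand.bin - cluster[-1].bin < min_separation:
            cluster.append(cand)
        else:
            if cluster:
                boundaries.append(center_of_valley(min(cluster, key=lambda x: (x.insulation, x.bin))))
            cluster = [cand]
    if cluster:
        boundaries.append(center_of_valley(min(cluster, key=lambda x: (x.insulation, x.bin))))
    tads = []
    finite = np.isfinite(values)
    n = len(values)
    seg_start = None
    bset = sorted(b.bin for b in boundaries)
    for i in range(n + 1):
        if i < n and finite[i]:
            if seg_start is None:
                seg_start = i
        elif seg_start is not None:
            inner = [b for b in bset if seg_start < b < i - 1]
            edges = [seg_start] + inner + [i]
            for s, e in zip(edges[:-1], edges[1:]):
                tads.append(
                    {
                        "chrom": track.chrom,
                        "start": s * track.bin_size,
                        "end": e * track.bin_size,
                        "size_bp": (e - s) * track.bin_size,
                    }
                )
            seg_start = None
    return boundaries, pd.DataFrame(tads)


def merge_replicate_boundaries(
    replicate_boundaries: list[list[Boundary]],
    min_support: int | None = None,
    max_dist_bins: int = 2,
) -> list[Boundary]:
    """Merge boundaries across replicates by single-linkage clustering.

    Boundary bins within ``max_dist_bins`` of each other (i.e. overlapping
    after one-bin dilation) collapse to their rounded mean bin; the merged
    record carries the number of distinct supporting replicates. Only
    clusters with support >= ``min_support`` (default: all replicates) are
    kept.
    """
    if min_support is None:
        min_support = len(replicate_boundaries)
    tagged = [
        (b.bin, rep, b.insulation)
        for rep, blist in enumerate(replicate_boundaries)
        for b in blist
    ]
    tagged.sort()
    merged: list[Boundary] = []
    cluster: list[tuple[int, int, float]] = []

    def flush() -> None:
        if not cluster:
            return
        support = len({rep for _, rep, _ in cluster})
        if support >= min_support:
            mean_bin = int(round(np.mean([b for b, _, _ in cluster])))
            ins = float(np.mean([v for _, _, v in cluster]))
            merged.append(Boundary(bin=mean_bin, insulation=ins, prominence=np.nan, support=support))

    for item in tagged:
        if cluster and item[0] - cluster[-1][0] > max_dist_bins:
            flush()
            cluster = []
        cluster.append(item)
    flush()
    return merged


def reconcile_boundaries(
    cond1_replicates: list[list[Boundary]],
    cond2_replicates: list[list[Boundary]],
    chrom: str,
    bin_size: int,
    min_support: int | None = None,
    max_dist_bins: int = 2,
) -> pd.DataFrame:
    """Cross-condition differential boundary table.

    Within each condition boundaries are replicate-merged (all-replicate
    support by default); merged boundaries from the two conditions that lie
    within ``max_dist_bins`` are 'common', the rest are condition-specific.
    """
    m1 = merge_replicate_boundaries(cond1_replicates, min_support, max_dist_bins)
    m2 = merge_replicate_boundaries(cond2_replicates, min_support, max_dist_bins)
    bins2 = np.array(sorted(b.bin for b in m2)) if m2 else np.array([], dtype=int)
    bins1 = np.array(sorted(b.bin for b in m1)) if m1 else np.array([], dtype=int)

    def nearest(bins: np.ndarray, b: int) -> int:
        if bins.size == 0:
            return np.iinfo(np.int32).max
        return int(np.min(np.abs(bins - b)))

    rows = []
    for b in m1:
        status = "common" if nearest(bins2, b.bin) <= max_dist_bins else "cond1_specific"
        rows.append((b.bin, b.insulation, b.support, status))
    for b in m2:
        if nearest(bins1, b.bin) > max_dist_bins:
            rows.append((b.bin, b.insulation, b.support, "cond2_specific"))
    rows.sort()
    return pd.DataFrame(
        [
            {
                "chrom": chrom,
                "start": b * bin_size,
                "end": (b + 1) * bin_size,
                "bin": b,
                "insulation": ins,
                "support": sup,
                "status": status,
            }
            for b, ins, sup, status in rows
        ]
    )
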