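"""Genomic-interval algebra, consensus peaks and permutation enrichment.

Interval sets are pandas frames with chrom/start/end (0-based half-open)
columns. Consensus peaks keep first-replicate peaks covered > 60% of their
length by a single peak in every other replicate. Enrichment of a query set
in an annotation is measured against length- and chromosome-matched random
placement within a workspace (1,000 permutations by default), with the +1
pseudo-count empirical p convention, Benjamini-Hochberg adjustment across
annotations, and a Fisher-exact 2x2 test for gene-set overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "sort_intervals",
    "merge_intervals",
    "intersect_intervals",
    "overlap_count",
    "overlap_bp",
    "consensus_peaks",
    "EnrichmentResult",
    "permutation_enrichment",
    "bh_adjust",
    "gene_set_overlap_test",
]


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    if np.any(df["start"] >= df["end"]):
        raise ValueError("interval with start >= end")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return _validate(df).sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or touching records are collapsed."""
    if df.empty:
        return df.copy()
    df = sort_intervals(df)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cs, ce = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= ce:
                ce = max(ce, e)
            else:
                rows.append((chrom, cs, ce))
                cs, ce = s, e
        rows.append((chrom, cs, ce))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Piecewise intersection of two interval sets (both merged internally)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    rows = []
    for chrom, ga in a.groupby("chrom", sort=False):
        gb = b[b["chrom"] == chrom]
        if gb.empty:
            continue
        bs = gb["start"].to_numpy()
        be = gb["end"].to_numpy()
        for s, e in zip(ga["start"].to_numpy(), ga["end"].to_numpy()):
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            for k in range(lo, hi):
                rows.append((chrom, max(s, bs[k]), min(e, be[k])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _per_query_overlap_bp(query: pd.DataFrame, annotation: pd.DataFrame) -> np.ndarray:
    """Shared base pairs between each query interval and the merged annotation."""
    ann = merge_intervals(annotation)
    out = np.zeros(len(query), dtype=np.int64)
    ann_by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy()) for c, g in ann.groupby("chrom")}
    for i, row in enumerate(query.itertuples(index=False)):
        got = ann_by_chrom.get(row.chrom)
        if got is None:
            continue
        bs, be = got
        lo = np.searchsorted(be, row.start, side="right")
        hi = np.searchsorted(bs, row.end, side="left")
        if hi > lo:
            out[i] = np.sum(
                np.minimum(row.end, be[lo:hi]) - np.maximum(row.start, bs[lo:hi])
            )
    return out


def overlap_count(query: pd.DataFrame, annotation: pd.DataFrame) -> int:
    """Number of query intervals sharing >= 1 bp with the annotation."""
    return int((_per_query_overlap_bp(query, annotation) > 0).sum())


def overlap_bp(query: pd.DataFrame, annotation: pd.DataFrame) -> int:
    """Base pairs shared between the merged query and merged annotation."""
    return int(_per_query_overlap_bp(merge_intervals(query), annotation).sum())


def consensus_peaks(
    replicate_sets: list[pd.DataFrame],
    min_overlap_frac: float = 0.6,
    min_support: int | None = None,
) -> pd.DataFrame:
    """Peaks of the first replicate covered > ``min_overlap_frac`` of their
    length by a single peak in every other required replicate.

    ``min_support`` counts the first set itself (default: all replicates).
    Output carries a ``support`` column.
    """
    if not (0 < min_overlap_frac <= 1):
        raise ValueError("min_overlap_frac must lie in (0, 1]")
    if len(replicate_sets) < 2:
        raise ValueError("need at least 2 replicate sets")
    if min_support is None:
        min_support = len(replicate_sets)
    first = sort_intervals(replicate_sets[0]).copy()
    support = np.ones(len(first), dtype=int)
    for other in replicate_sets[1:]:
        other = sort_intervals(other)
        by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy()) for c, g in other.groupby("chrom")}
        for i, row in enumerate(first.itertuples(index=False)):
            got = by_chrom.get(row.chrom)
            if got is None:
                continue
            bs, be = got
            lo = np.searchsorted(be, row.start, side="right")
            hi = np.searchsorted(bs, row.end, side="left")
            length = row.end - row.start
            for k in range(lo, hi):
                cov = min(row.end, be[k]) - max(row.start, bs[k])
                if cov / length > min_overlap_frac:
                    support[i] += 1
                    break
    first["support"] = support
    return first[first["support"] >= min_support].reset_index(drop=True)


@dataclass
class EnrichmentResult:
    annotation: str
    observed: float
    perm_mean: float
    perm_sd: float
    fold: float
    p_enriched: float
    p_depleted: float
    n_permutations: int
    seed: int
    mode: str
    q: float = float("nan")


def _random_starts(
    rng: np.random.Generator,
    lengths: np.ndarray,
    ws_start: np.ndarray,
    ws_end: np.ndarray,
    chrom: str,
) -> np.ndarray:
    """Uniform random start for each query length within the workspace,
    weighting each workspace interval by its number of valid start slots."""
    ws_len = ws_end - ws_start
    starts = np.empty(len(lengths), dtype=np.int64)
    for i, length in enumerate(lengths):
        slots = np.maximum(ws_len - length + 1, 0)
        cum = np.cumsum(slots)
        if cum[-1] <= 0:
            raise ValueError(f"no workspace room for a {length} bp interval on {chrom}")
        pick = rng.integers(cum[-1])
        k = int(np.searchsorted(cum, pick, side="right"))
        starts[i] = ws_start[k] + pick - (cum[k - 1] if k else 0)
    return starts


def _overlap_stats(starts: np.ndarray, ends: np.ndarray, ann_s: np.ndarray, ann_e: np.ndarray) -> tuple[int, int]:
    """(intervals touched, shared bp) of query arrays vs a merged annotation."""
    lo = np.searchsorted(ann_e, starts, side="right")
    hi = np.searchsorted(ann_s, ends, side="left")
    touched = int((hi > lo).sum())
    bp = 0
    for s, e, a, b in zip(starts, ends, lo, hi):
        if b > a:
            bp += int(np.sum(np.minimum(e, ann_e[a:b]) - np.maximum(s, ann_s[a:b])))
    return touched, bp


def permutation_enrichment(
    query: pd.DataFrame,
    annotation: pd.DataFrame,
    workspace: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "count",
    name: str = "annotation",
) -> EnrichmentResult:
    """Observed/expected overlap of ``query`` with ``annotation`` against
    chromosome- and length-matched uniform random placement in ``workspace``.

    ``mode='count'`` counts query intervals touching the annotation;
    ``mode='bp'`` sums shared base pairs. Empirical p uses the +1
    pseudo-count: p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if mode not in ("count", "bp"):
        raise ValueError("mode must be 'count' or 'bp'")
    measure = overlap_count if mode == "count" else overlap_bp
    query = sort_intervals(query)
    ws = merge_intervals(workspace)
    ws_by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy()) for c, g in ws.groupby("chrom")
    }
    lengths_by_chrom = {
        c: (g["end"] - g["start"]).to_numpy() for c, g in query.groupby("chrom")
    }
    for chrom in lengths_by_chrom:
        if chrom not in ws_by_chrom:
            raise ValueError(f"workspace has no intervals on chromosome {chrom}")
    observed = measure(query, annotation)
    ann = merge_intervals(annotation)
    ann_by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy()) for c, g in ann.groupby("chrom")
    }
    rng = np.random.default_rng(seed)
    permuted = np.zeros(n_perm)
    for i in range(n_perm):
        for chrom, lengths in lengths_by_chrom.items():
            ws_s, ws_e = ws_by_chrom[chrom]
            starts = _random_starts(rng, lengths, ws_s, ws_e, chrom)
            got = ann_by_chrom.get(chrom)
            if got is None:
                continue
            touched, bp = _overlap_stats(starts, starts + lengths, got[0], got[1])
            permuted[i] += touched if mode == "count" else bp
    perm_mean = float(permuted.mean())
    fold = observed / perm_mean if perm_mean > 0 else float("inf")
    p_enr = (1 + np.sum(permuted >= observed)) / (n_perm + 1)
    p_dep = (1 + np.sum(permuted <= observed)) / (n_perm + 1)
    return EnrichmentResult(
        annotation=name,
        observed=float(observed),
        perm_mean=perm_mean,
        perm_sd=float(permuted.std(ddof=1)) if n_perm > 1 else float("nan"),
        fold=float(fold),
        p_enriched=float(p_enr),
        p_depleted=float(p_dep),
        n_permutations=n_perm,
        seed=seed,
        mode=mode,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_set_overlap_test(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
) -> dict[str, float]:
    """Fisher's exact test on the 2x2 in/out membership table.

    Returns the two-sided p, the sample odds ratio (0.5 continuity
    correction applied and flagged when a cell is zero), and the table.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe - a - b)
    table = np.array([[n11, n12], [n21, n22]])
    degenerate = (n11 + n12 == 0) or (n21 + n22 == 0) or (n11 + n21 == 0) or (n12 + n22 == 0)
    if degenerate:
        return {
            "odds_ratio": float("nan"),
            "p": 1.0,
            "table": table,
            "continuity_corrected": False,
            "degenerate": True,
        }
    _, p = stats.fisher_exact(table, alternative="two-sided")
    corrected = (table == 0).any()
    t = table + 0.5 if corrected else table
    oddsr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {
        "odds_ratio": float(oddsr),
        "p": float(p),
        "table": table,
        "continuity_corrected": bool(corrected),
        "degenerate": False,
    }
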