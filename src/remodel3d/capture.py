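"""Promoter-capture interaction filtering and differential classification.

Works on ibed-like tables of bait / other-end (OE) anchors with a
CHiCAGO-style significance score per replicate. The pipeline keeps
interactions scoring above 5 outside bait-to-bait pairs, forms a replicate
consensus (score > 5 in k of n replicates), merges other-end anchors per
bait with single-linkage up to a 10 kb gap, and classifies region-level
calls as gained / lost / maintained by the difference of mean
asinh-transformed scores between conditions (|delta| > 1). A three-stage
time-course partitions treatment-gained interactions into gained-and-lost
versus gained-and-maintained at the recovery stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "IBED_COLUMNS",
    "load_and_filter",
    "consensus_and_diff",
    "per_bait_connectivity",
    "timecourse_partition",
]

IBED_COLUMNS = [
    "bait_chr",
    "bait_start",
    "bait_end",
    "bait_name",
    "oe_chr",
    "oe_start",
    "oe_end",
    "oe_name",
    "N_reads",
    "score",
]


def load_and_filter(
    records: pd.DataFrame,
    score_min: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records with score strictly above ``score_min`` that are not
    bait-to-bait (an other end named anything but '.' is itself a bait).

    Returns the filtered frame and the counts dropped by each rule.
    """
    df = records.copy()
    missing = [c for c in IBED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing ibed columns: {missing}")
    bad_score = df.index[df["score"] < 0]
    if len(bad_score):
        raise ValueError(f"negative score at line {int(bad_score[0]) + 1}")
    bad_anchor = df.index[(df["bait_end"] <= df["bait_start"]) | (df["oe_end"] <= df["oe_start"])]
    if len(bad_anchor):
        raise ValueError(f"malformed anchor at line {int(bad_anchor[0]) + 1}")
    is_b2b = df["oe_name"].astype(str) != "."
    low = df["score"] <= score_min
    kept = df[~is_b2b & ~low].reset_index(drop=True)
    dropped = {
        "bait_to_bait": int(is_b2b.sum()),
        "low_score": int((low & ~is_b2b).sum()),
    }
    return kept, dropped


def _merge_oe_regions(df: pd.DataFrame, merge_gap: int) -> pd.DataFrame:
    """Single-linkage merge of other-end anchors per bait (cis only).

    Adds a ``region_id`` of the form 'bait|chrom:start-end' identifying the
    merged other-end region each record belongs to.
    """
    df = df.sort_values(["bait_name", "oe_chr", "oe_start"], kind="stable").reset_index(drop=True)
    region_ids = np.empty(len(df), dtype=object)
    for (_bait, _chrom), idx in df.groupby(["bait_name", "oe_chr"], sort=False).groups.items():
        idx = np.asarray(idx)
        starts = df.loc[idx, "oe_start"].to_numpy()
        ends = df.loc[idx, "oe_end"].to_numpy()
        cluster_start = starts[0]
        cluster_end = ends[0]
        members = [idx[0]]
        clusters = []
        for k in range(1, len(idx)):
            if starts[k] - cluster_end <= merge_gap:
                cluster_end = max(cluster_end, ends[k])
                members.append(idx[k])
            else:
                clusters.append((cluster_start, cluster_end, members))
                cluster_start, cluster_end, members = starts[k], ends[k], [idx[k]]
        clusters.append((cluster_start, cluster_end, members))
        for cs, ce, mem in clusters:
            rid = f"{_bait}|{_chrom}:{cs}-{ce}"
            for m in mem:
                region_ids[m] = rid
    df["region_id"] = region_ids
    return df


def _region_scores(
    replicates: list[pd.DataFrame],
    merge_gap: int,
) -> pd.DataFrame:
    """Per merged region x replicate score matrix (max member score; absent = 0)."""
    tagged = []
    for rep, df in enumerate(replicates):
        d = df.copy()
        d["replicate"] = rep
        tagged.append(d)
    allrec = pd.concat(tagged, ignore_index=True)
    allrec = _merge_oe_regions(allrec, merge_gap)
    pivot = (
        allrec.groupby(["region_id", "replicate"])["score"].max().unstack(fill_value=0.0)
    )
    pivot = pivot.reindex(columns=range(len(replicates)), fill_value=0.0)
    meta = allrec.groupby("region_id").agg(
        bait_name=("bait_name", "first"),
        bait_chr=("bait_chr", "first"),
        bait_start=("bait_start", "min"),
        bait_end=("bait_end", "max"),
        oe_chr=("oe_chr", "first"),
        oe_start=("oe_start", "min"),
        oe_end=("oe_end", "max"),
    )
    return meta.join(pivot)


def consensus_and_diff(
    cond1_replicates: list[pd.DataFrame],
    cond2_replicates: list[pd.DataFrame],
    k_of_n: int = 2,
    score_min: float = 5.0,
    asinh_delta: float = 1.0,
    merge_gap: int = 10_000,
) -> pd.DataFrame:
    """Region-merged differential calls between two replicate sets.

    A region is condition-significant when its score exceeds ``score_min``
    in at least ``k_of_n`` replicates of that condition. Mean asinh scores
    are taken over all replicates with absent records counted as score 0.
    Classes: gained when mean2 - mean1 > ``asinh_delta``, lost when
    mean1 - mean2 > ``asinh_delta``, else maintained (among regions
    significant in at least one condition).
    """
    n1, n2 = len(cond1_replicates), len(cond2_replicates)
    if k_of_n > max(n1, n2):
        raise ValueError(f"k_of_n={k_of_n} exceeds replicate count")
    # merge other ends on the union of all records so both conditions share
    # the same region universe
    tagged = []
    for cond, reps in (("cond1", cond1_replicates), ("cond2", cond2_replicates)):
        for rep, df in enumerate(reps):
            d = df.copy()
            d["condition"] = cond
            d["replicate"] = rep
            tagged.append(d)
    allrec = _merge_oe_regions(pd.concat(tagged, ignore_index=True), merge_gap)

    meta = allrec.groupby("region_id").agg(
        bait_name=("bait_name", "first"),
        bait_chr=("bait_chr", "first"),
        oe_chr=("oe_chr", "first"),
        oe_start=("oe_start", "min"),
        oe_end=("oe_end", "max"),
        bait_start=("bait_start", "min"),
        bait_end=("bait_end", "max"),
    )
    out_rows = {}
    for cond, n_rep in (("cond1", n1), ("cond2", n2)):
        sub = allrec[allrec["condition"] == cond]
        pivot = sub.groupby(["region_id", "replicate"])["score"].max().unstack()
        pivot = pivot.reindex(index=meta.index, columns=range(n_rep)).fillna(0.0)
        out_rows[f"{cond}_n_sig"] = (pivot > score_min).sum(axis=1)
        out_rows[f"{cond}_mean_asinh"] = np.arcsinh(pivot).mean(axis=1)
    res = meta.assign(**out_rows)
    res["cond1_significant"] = res["cond1_n_sig"] >= k_of_n
    res["cond2_significant"] = res["cond2_n_sig"] >= k_of_n
    res = res[res["cond1_significant"] | res["cond2_significant"]].copy()
    delta = res["cond2_mean_asinh"] - res["cond1_mean_asinh"]
    res["delta_asinh"] = delta
    res["class"] = np.where(
        delta > asinh_delta, "gained", np.where(delta < -asinh_delta, "lost", "maintained")
    )
    # midpoint-to-midpoint genomic distance for cis pairs
    cis = res["bait_chr"] == res["oe_chr"]
    bait_mid = (res["bait_start"] + res["bait_end"]) / 2
    oe_mid = (res["oe_start"] + res["oe_end"]) / 2
    res["distance"] = np.where(cis, np.abs(bait_mid - oe_mid), np.nan)
    return res.reset_index()


def per_bait_connectivity(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Distinct significant other-end regions per bait, per condition.

    Returns the per-bait paired table and summary means, plus log10 distance
    summaries stratified by differential class.
    """
    per_bait = calls.groupby("bait_name").agg(
        n_oe_cond1=("cond1_significant", "sum"),
        n_oe_cond2=("cond2_significant", "sum"),
    )
    summary: dict[str, float] = {
        "mean_oe_per_bait_cond1": float(per_bait["n_oe_cond1"].mean()),
        "mean_oe_per_bait_cond2": float(per_bait["n_oe_cond2"].mean()),
        "n_baits": int(len(per_bait)),
    }
    for cls in ("gained", "lost", "maintained"):
        d = calls.loc[(calls["class"] == cls) & (calls["distance"] > 0), "distance"]
        summary[f"median_log10_dist_{cls}"] = (
            float(np.log10(d).median()) if len(d) else float("nan")
        )
    return per_bait.reset_index(), summary


def region_overlap_match(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    max_gap: int = 0,
) -> np.ndarray:
    """True per query row when ``reference`` holds a region for the same bait
    whose other-end interval lies within ``max_gap`` of the query's."""
    hits = np.zeros(len(query), dtype=bool)
    ref_by_bait = {
        bait: grp[["oe_chr", "oe_start", "oe_end"]].to_numpy(dtype=object)
        for bait, grp in reference.groupby("bait_name")
    }
    for i, row in enumerate(query.itertuples(index=False)):
        cand = ref_by_bait.get(row.bait_name)
        if cand is None:
            continue
        for chrom, s, e in cand:
            if chrom == row.oe_chr and row.oe_start <= e + max_gap and s <= row.oe_end + max_gap:
                hits[i] = True
                break
    return hits


def timecourse_partition(
    gained_at_treated: pd.DataFrame,
    recovery_significant: set[str] | pd.DataFrame,
    max_gap: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Split treatment-gained interactions by persistence at recovery.

    A gained interaction still significant (consensus rule) at the recovery
    stage is 'gained_and_maintained'; otherwise 'gained_and_lost'.
    ``recovery_significant`` is either a set of region ids on the same
    region universe, or a call table matched by bait and other-end overlap.
    Returns the labelled table and counts with the percentage lost.
    """
    gained = gained_at_treated[gained_at_treated["class"] == "gained"].copy()
    if gained.empty:
        raise ValueError("empty treated-stage gained set")
    if isinstance(recovery_significant, pd.DataFrame):
        maintained = region_overlap_match(gained, recovery_significant, max_gap=max_gap)
    else:
        recovered = set(recovery_significant)
        maintained = np.array([rid in recovered for rid in gained["region_id"]])
    gained["timecourse_class"] = np.where(maintained, "gained_and_maintained", "gained_and_lost")
    n_lost = int((gained["timecourse_class"] == "gained_and_lost").sum())
    n_total = int(len(gained))
    stats = {
        "n_gained": n_total,
        "n_gained_and_lost": n_lost,
        "n_gained_and_maintained": n_total - n_lost,
        "pct_lost": 100.0 * n_lost / n_total,
    }
    return gained, stats
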