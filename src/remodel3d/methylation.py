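"""Methylation-array beta values, M-values, DMR calling and region summaries.

Beta values come from methylated/unmethylated intensities as
beta = M / (U + M + 100); probes whose detection p exceeds 0.01 are masked.
Differentially methylated regions (DMRs) chain consecutive probes whose
group-mean beta difference exceeds 0.30 with the same sign and inter-probe
gaps of at most 1,000 nt, keeping chains of at least two probes whose
region-mean |delta beta| also exceeds 0.30. Region summaries additionally
flag re-methylated intervals (> 0.30 beta gain from treated to recovery).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "beta_from_signals",
    "m_transform",
    "call_dmrs",
    "region_methylation_summary",
]

_BETA_OFFSET = 100.0
_DETECTION_P = 0.01
_CLIP_EPS = 1e-6


def beta_from_signals(
    meth: np.ndarray,
    unmeth: np.ndarray,
    detection_p: np.ndarray | None = None,
) -> np.ndarray:
    """beta = M / (U + M + 100), NaN where detection p > 0.01."""
    m = np.asarray(meth, dtype=float)
    u = np.asarray(unmeth, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("negative intensity")
    beta = m / (u + m + _BETA_OFFSET)
    if detection_p is not None:
        beta = np.where(np.asarray(detection_p, dtype=float) > _DETECTION_P, np.nan, beta)
    return beta


def m_transform(beta: np.ndarray, eps: float = _CLIP_EPS) -> np.ndarray:
    """Logit transform M = log2(beta / (1 - beta)), clipping beta to
    [eps, 1 - eps]; NaN passes through."""
    b = np.asarray(beta, dtype=float)
    finite = np.isfinite(b)
    if np.any((b[finite] < 0) | (b[finite] > 1)):
        raise ValueError("beta outside [0, 1]")
    b = np.clip(b, eps, 1 - eps)
    return np.log2(b / (1 - b))


def _probe_deltas(
    table: pd.DataFrame,
    beta: pd.DataFrame,
    group1: list[str],
    group2: list[str],
) -> pd.Series:
    for s in list(group1) + list(group2):
        if s not in beta.columns:
            raise KeyError(f"unknown sample id {s!r}")
    return beta[list(group2)].mean(axis=1) - beta[list(group1)].mean(axis=1)


def call_dmrs(
    table: pd.DataFrame,
    beta: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    max_gap: int = 1000,
    min_probes: int = 2,
    min_delta: float = 0.30,
) -> pd.DataFrame:
    """Chain candidate probes into differentially methylated regions.

    ``table`` holds probe/chrom/pos rows aligned with the per-sample beta
    frame. Candidate probes have |group2 - group1 mean beta| > ``min_delta``;
    runs of same-sign candidates with inter-probe gaps <= ``max_gap`` become
    regions, kept when they hold >= ``min_probes`` probes and the region
    mean |delta| stays > ``min_delta``. Direction is hypo when group2 is
    lower than group1.
    """
    delta = _probe_deltas(table, beta, group1, group2)
    df = table[["probe", "chrom", "pos"]].copy()
    df["delta"] = delta.to_numpy()
    df = df[np.isfinite(df["delta"])].sort_values(["chrom", "pos"], kind="stable")
    cand = df[np.abs(df["delta"]) > min_delta]
    regions = []
    for chrom, grp in cand.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        dlt = grp["delta"].to_numpy()
        start = 0
        for k in range(1, len(grp) + 1):
            new_chain = (
                k == len(grp)
                or pos[k] - pos[k - 1] > max_gap
                or np.sign(dlt[k]) != np.sign(dlt[start])
            )
            if new_chain:
                n = k - start
                mean_d = float(np.mean(dlt[start:k]))
                if n >= min_probes and abs(mean_d) > min_delta:
                    regions.append(
                        {
                            "chrom": chrom,
                            "start": int(pos[start]),
                            "end": int(pos[k - 1]) + 1,
                            "n_probes": n,
                            "mean_delta": mean_d,
                            "direction": "hypo" if mean_d < 0 else "hyper",
                        }
                    )
                start = k
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_probes", "mean_delta", "direction"])


def region_methylation_summary(
    table: pd.DataFrame,
    beta: pd.DataFrame,
    intervals: pd.DataFrame,
    groups: dict[str, list[str]],
    remethylation_delta: float = 0.30,
) -> pd.DataFrame:
    """Per-interval group-mean beta; intervals without probes are NaN.

    When ``groups`` contains 'treated' and 'recovery', intervals with
    mean beta gain above ``remethylation_delta`` are flagged re-methylated.
    """
    rows = []
    for iv in intervals.itertuples(index=False):
        sel = (table["chrom"] == iv.chrom) & (table["pos"] >= iv.start) & (table["pos"] < iv.end)
        row = {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "n_probes": int(sel.sum())}
        for gname, samples in groups.items():
            vals = beta.loc[sel.to_numpy(), list(samples)].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"mean_beta_{gname}"] = float(vals.mean()) if vals.size else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if "treated" in groups and "recovery" in groups:
        gain = out["mean_beta_recovery"] - out["mean_beta_treated"]
        out["delta_recovery_treated"] = gain
        out["remethylated"] = gain > remethylation_delta
    return out
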