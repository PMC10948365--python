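"""A/B compartment calling, switch classification, saddle and A:B ratio.

The leading eigenvector (PC1) of the Pearson correlation matrix of the O/E
contact matrix partitions bins into the open, gene-dense A compartment
(PC1 > 0 after gene-density orientation) and the closed B compartment
(PC1 < 0). Cross-condition switch classes (A->A, B->B, A->B, B->A) come
from a per-condition replicate consensus on PC1 sign; the saddle statistic
summarizes compartmentalization strength as
log2((AA + BB) / (AB + BA)) over the extreme 20% of PC1 ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .matrix import OEMatrix

__all__ = [
    "CompartmentTrack",
    "SaddleResult",
    "compute_pc1",
    "segment_track",
    "classify_switches",
    "saddle_strength",
    "ab_interaction_ratio",
]

_CLASSES = ("A->A", "B->B", "A->B", "B->A")


@dataclass
class CompartmentTrack:
    chrom: str
    bin_size: int
    pc1: np.ndarray  # NaN at masked bins
    labels: np.ndarray  # 'A', 'B' or 'NA' per bin
    gene_density_corr: float
    ambiguous: bool  # |orientation correlation| < 0.1


@dataclass
class SaddleResult:
    saddle: np.ndarray  # (Q, Q) mean log2 O/E between PC1-quantile groups
    corner_means: dict[str, float]  # AA, BB, AB, BA mean O/E
    strength: float  # log2((AA+BB)/(AB+BA))
    n_quantiles: int
    corner_frac: float


def _labels_from_pc1(pc1: np.ndarray) -> np.ndarray:
    labels = np.full(pc1.shape, "NA", dtype=object)
    labels[pc1 > 0] = "A"
    labels[pc1 < 0] = "B"
    return labels


def compute_pc1(
    oe: OEMatrix,
    gene_density: np.ndarray,
    smooth_bins: int = 3,
    min_bins: int = 10,
    ambiguity_corr: float = 0.1,
) -> CompartmentTrack:
    """Leading eigenvector of the O/E Pearson correlation matrix.

    ``smooth_bins`` applies a centered running mean over that many bins
    (the ~100 kb window at 50 kb resolution; even values are widened to the
    next odd width so the filter stays phase-neutral); set to 0/1 to
    disable. The sign is flipped so the correlation with ``gene_density``
    is non-negative; chromosomes where |correlation| < ``ambiguity_corr``
    are flagged ambiguous.
    """
    mask = oe.mask.copy()
    if mask.sum() < min_bins:
        raise ValueError(f"only {int(mask.sum())} unmasked bins (< {min_bins})")
    sub = oe.oe[np.ix_(mask, mask)]
    # a residual NaN can occur at distances with no unmasked pair; treat as
    # the neutral O/E value so the correlation stays defined
    sub = np.where(np.isfinite(sub), sub, 1.0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    const = ~np.isfinite(corr).all(axis=0)  # zero-variance columns
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    try:
        k = corr.shape[0]
        evals, evecs = eigh(corr, subset_by_index=[k - 1, k - 1])
    except Exception as exc:  # pragma: no cover - solver failure path
        raise RuntimeError(f"eigen-decomposition failed on {oe.chrom}") from exc
    if evals[0] <= 1.0 + 1e-8:
        # leading eigenvalue of a correlation matrix at 1: no shared
        # structure (e.g. constant O/E); report a null track
        vec = np.zeros(corr.shape[0])
    else:
        vec = evecs[:, 0] * np.sqrt(evals[0])
    pc1 = np.full(oe.n_bins, np.nan)
    pc1[mask] = vec
    if smooth_bins and smooth_bins > 1:
        pc1 = _running_mean_nan(pc1, smooth_bins | 1)  # force odd, centered
        pc1[~mask] = np.nan
    gd = np.asarray(gene_density, dtype=float)
    ok = mask & np.isfinite(gd) & np.isfinite(pc1)
    if ok.sum() >= 3 and np.std(pc1[ok]) > 0 and np.std(gd[ok]) > 0:
        r = float(np.corrcoef(pc1[ok], gd[ok])[0, 1])
    else:
        r = 0.0
    if r < 0:
        pc1 = -pc1
        r = -r
    return CompartmentTrack(
        chrom=oe.chrom,
        bin_size=oe.bin_size,
        pc1=pc1,
        labels=_labels_from_pc1(pc1),
        gene_density_corr=r,
        ambiguous=abs(r) < ambiguity_corr,
    )


def _running_mean_nan(x: np.ndarray, w: int) -> np.ndarray:
    out = np.full_like(x, np.nan)
    n = len(x)
    half = (w - 1) // 2
    for i in range(n):
        window = x[max(0, i - half) : min(n, i + half + 1)]
        vals = window[np.isfinite(window)]
        if vals.size:
            out[i] = vals.mean()
    return out


def segment_track(track: CompartmentTrack) -> pd.DataFrame:
    """Maximal runs of identical label as (chrom, start, end, label) rows."""
    rows = []
    labels = track.labels
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        rows.append(
            {
                "chrom": track.chrom,
                "start": i * track.bin_size,
                "end": j * track.bin_size,
                "label": labels[i],
            }
        )
        i = j
    return pd.DataFrame(rows)


def _condition_consensus(tracks: list[CompartmentTrack], min_rep_agree: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean PC1 and consensus label per bin across replicate tracks."""
    pcs = np.vstack([t.pc1 for t in tracks])
    any_finite = np.isfinite(pcs).any(axis=0)
    mean_pc1 = np.full(pcs.shape[1], np.nan)
    mean_pc1[any_finite] = np.nanmean(pcs[:, any_finite], axis=0)
    signs = np.sign(pcs)  # NaN propagates
    n_rep = len(tracks)
    labels = np.full(pcs.shape[1], "NA", dtype=object)
    for b in range(pcs.shape[1]):
        mp = mean_pc1[b]
        if not np.isfinite(mp) or mp == 0:
            continue
        consensus = np.sign(mp)
        agree = np.sum(signs[:, b] == consensus)
        if agree / n_rep >= min_rep_agree:
            labels[b] = "A" if consensus > 0 else "B"
    return mean_pc1, labels


def classify_switches(
    tracks_cond1: list[CompartmentTrack],
    tracks_cond2: list[CompartmentTrack],
    min_rep_agree: float = 1.0,
) -> pd.DataFrame:
    """Per-bin switch classes between two replicate sets of PC1 tracks.

    Within a condition the bin label is the sign of the mean PC1 across
    replicates, kept only if at least ``min_rep_agree`` of replicates share
    that sign; bins NA in either condition are NA overall. Returns a frame
    with chrom/start/end, per-condition mean PC1 and label, and class.
    """
    all_tracks = tracks_cond1 + tracks_cond2
    n = all_tracks[0].pc1.shape[0]
    bs = all_tracks[0].bin_size
    for t in all_tracks:
        if t.pc1.shape[0] != n or t.bin_size != bs:
            raise ValueError("mismatched bin grids between tracks")
    pc1_1, lab1 = _condition_consensus(tracks_cond1, min_rep_agree)
    pc1_2, lab2 = _condition_consensus(tracks_cond2, min_rep_agree)
    cls = np.full(n, "NA", dtype=object)
    for b in range(n):
        if lab1[b] != "NA" and lab2[b] != "NA":
            cls[b] = f"{lab1[b]}->{lab2[b]}"
    chrom = all_tracks[0].chrom
    starts = np.arange(n) * bs
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bs,
            "pc1_cond1": pc1_1,
            "pc1_cond2": pc1_2,
            "label_cond1": lab1,
            "label_cond2": lab2,
            "class": cls,
        }
    )


def switch_summary(switch_table: pd.DataFrame) -> dict[str, float]:
    """Class counts plus switching fraction and % of switches that are B->A."""
    counts = {c: int((switch_table["class"] == c).sum()) for c in _CLASSES}
    classified = sum(counts.values())
    switching = counts["A->B"] + counts["B->A"]
    out: dict[str, float] = {f"n_{c}": v for c, v in counts.items()}
    out["n_classified"] = classified
    out["switch_fraction"] = switching / classified if classified else float("nan")
    out["pct_activation"] = 100.0 * counts["B->A"] / switching if switching else float("nan")
    return out


def saddle_strength(
    oe: OEMatrix,
    track: CompartmentTrack,
    n_quantiles: int = 50,
    corner_frac: float = 0.2,
) -> SaddleResult:
    """Saddle matrix over PC1-quantile groups and compartment strength.

    Bins are ranked by PC1 into ``n_quantiles`` equal-occupancy groups; the
    saddle entry (q1, q2) is the mean log2 O/E over bin pairs between the
    groups. Corner means AA/BB/AB/BA are mean O/E between the top and
    bottom ``corner_frac`` of PC1 ranks; strength = log2((AA+BB)/(AB+BA)).
    """
    ok = track.labels != "NA"
    ok &= oe.mask
    idx = np.where(ok)[0]
    if idx.size < n_quantiles:
        raise ValueError("fewer unmasked bins than quantile groups")
    order = idx[np.argsort(track.pc1[idx], kind="stable")]  # ascending: B end first
    groups = np.array_split(order, n_quantiles)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_oe = np.log2(oe.oe)
    saddle = np.full((n_quantiles, n_quantiles), np.nan)
    for a in range(n_quantiles):
        for b in range(a, n_quantiles):
            block = log_oe[np.ix_(groups[a], groups[b])]
            vals = block[np.isfinite(block)]
            if vals.size:
                saddle[a, b] = saddle[b, a] = vals.mean()

    n_corner = max(1, int(round(corner_frac * order.size)))
    bottom = order[:n_corner]  # most negative PC1: B
    top = order[-n_corner:]  # most positive PC1: A
    def corner(rows: np.ndarray, cols: np.ndarray) -> float:
        block = oe.oe[np.ix_(rows, cols)]
        if rows is cols:
            iu = np.triu_indices(len(rows), k=1)
            block = block[iu]
        vals = block[np.isfinite(block)]
        if vals.size == 0:
            raise ValueError("saddle corner has no unmasked pairs")
        return float(vals.mean())

    aa = corner(top, top)
    bb = corner(bottom, bottom)
    ab = corner(top, bottom)
    corners = {"AA": aa, "BB": bb, "AB": ab, "BA": ab}
    strength = float(np.log2((aa + bb) / (ab + ab))) if (ab > 0) else float("nan")
    return SaddleResult(
        saddle=saddle,
        corner_means=corners,
        strength=strength,
        n_quantiles=n_quantiles,
        corner_frac=corner_frac,
    )


def ab_interaction_ratio(
    oe: OEMatrix,
    track: CompartmentTrack,
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Per-window log2 ratio of O/E contact with A versus B compartment bins.

    Each window sums O/E from its bins to every A-labeled and every
    B-labeled bin outside the window itself; windows with a zero denominator
    are reported missing (NaN) with ``no_b_contact`` flagged.
    """
    if window_bp % oe.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window_bp // oe.bin_size
    n = oe.n_bins
    a_bins = np.where(track.labels == "A")[0]
    b_bins = np.where(track.labels == "B")[0]
    rows = []
    oe_filled = np.where(np.isfinite(oe.oe), oe.oe, 0.0)
    for start in range(0, n, w):
        win = np.arange(start, min(start + w, n))
        a_out = np.setdiff1d(a_bins, win, assume_unique=True)
        b_out = np.setdiff1d(b_bins, win, assume_unique=True)
        a_sum = oe_filled[np.ix_(win, a_out)].sum() if a_out.size else 0.0
        b_sum = oe_filled[np.ix_(win, b_out)].sum() if b_out.size else 0.0
        flagged = b_sum <= 0 or a_sum <= 0
        ratio = np.nan if flagged else float(np.log2(a_sum / b_sum))
        rows.append(
            {
                "chrom": oe.chrom,
                "start": start * oe.bin_size,
                "end": int(win[-1] + 1) * oe.bin_size,
                "log2_ab_ratio": ratio,
                "no_b_contact": flagged,
            }
        )
    return pd.DataFrame(rows)
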