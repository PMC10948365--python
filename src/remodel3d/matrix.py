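"""Binned intra-chromosomal contact matrices: ICE balancing and O/E.

Dense symmetric per-chromosome matrices. ICE (iterative correction)
equalizes bin coverage with a multiplicative bias vector; the O/E transform
divides each diagonal by its mean over unmasked pairs, removing the
distance-decay so compartment structure becomes visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContactMatrix",
    "BalancedMatrix",
    "OEMatrix",
    "bin_contacts",
    "merge_matrices",
    "ice_balance",
    "expected_profile",
    "observed_over_expected",
]


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    matrix: np.ndarray  # (n, n) symmetric non-negative counts
    mask: np.ndarray  # (n,) True = valid bin

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("contact matrix must be non-negative")
        self.matrix = m
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class BalancedMatrix:
    chrom: str
    bin_size: int
    balanced: np.ndarray  # C[i,j] / (bias[i] * bias[j]), zero at masked bins
    bias: np.ndarray  # per-bin bias, NaN at masked bins, mean 1 over unmasked
    mask: np.ndarray
    converged: bool
    n_iter: int

    @property
    def n_bins(self) -> int:
        return self.balanced.shape[0]


@dataclass
class OEMatrix:
    chrom: str
    bin_size: int
    oe: np.ndarray  # NaN at masked bins / unavailable distances
    expected: np.ndarray  # expected[d], NaN where no unmasked pair
    mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.oe.shape[0]


def bin_contacts(
    pos1: np.ndarray,
    pos2: np.ndarray,
    count: np.ndarray,
    chrom: str,
    chrom_length: int,
    bin_size: int,
) -> ContactMatrix:
    """Accumulate intra-chromosomal pairs into a symmetric binned matrix."""
    pos1 = np.asarray(pos1, dtype=np.int64)
    pos2 = np.asarray(pos2, dtype=np.int64)
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("negative contact counts")
    if np.any((pos1 < 0) | (pos1 >= chrom_length) | (pos2 < 0) | (pos2 >= chrom_length)):
        raise ValueError(f"pair position outside chromosome {chrom} [0, {chrom_length})")
    n = int(np.ceil(chrom_length / bin_size))
    b1 = pos1 // bin_size
    b2 = pos2 // bin_size
    m = np.zeros((n, n))
    np.add.at(m, (b1, b2), count)
    off = m - np.diag(np.diag(m))
    m = np.diag(np.diag(m)) + off + off.T  # mirror off-diagonal, diagonal once
    mask = m.sum(axis=0) > 0
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=m, mask=mask)


def merge_matrices(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of replicate matrices with identical shape."""
    first = matrices[0]
    total = np.zeros_like(first.matrix)
    for cm in matrices:
        if cm.matrix.shape != first.matrix.shape or cm.bin_size != first.bin_size:
            raise ValueError("replicate matrices have mismatched grids")
        total += cm.matrix
    return ContactMatrix(
        chrom=first.chrom, bin_size=first.bin_size, matrix=total, mask=total.sum(axis=0) > 0
    )


def ice_balance(
    cm: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_low_frac: float = 0.02,
) -> BalancedMatrix:
    """Iterative correction: scale rows/columns until coverage is uniform.

    Bins with zero marginal, plus the lowest ``mask_low_frac`` quantile of
    nonzero marginals, are masked before balancing. Convergence is reached
    when the coefficient of variation of unmasked row sums drops below
    ``tol``. The bias vector is normalized to mean 1 over unmasked bins.
    """
    marg = cm.matrix.sum(axis=0)
    mask = cm.mask & (marg > 0)
    if mask_low_frac > 0 and mask.sum() > 2:
        thresh = np.quantile(marg[mask], mask_low_frac)
        mask = mask & (marg > thresh)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 unmasked bins; cannot balance")

    w = cm.matrix.copy()
    w[~mask, :] = 0.0
    w[:, ~mask] = 0.0
    bias = np.ones(cm.n_bins)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s = w.sum(axis=0)
        sm = s[mask]
        cv = sm.std() / sm.mean()
        if cv < tol:
            converged = True
            break
        scale = np.ones_like(s)
        scale[mask] = sm / sm.mean()
        bias *= scale
        w /= np.outer(scale, scale)
    bias_out = np.where(mask, bias, np.nan)
    mean_b = np.nanmean(bias_out)
    bias_out /= mean_b
    w *= mean_b**2  # keep balanced == C / (bias_i * bias_j) after normalization
    return BalancedMatrix(
        chrom=cm.chrom,
        bin_size=cm.bin_size,
        balanced=w,
        bias=bias_out,
        mask=mask,
        converged=converged,
        n_iter=n_iter,
    )


def expected_profile(bm: BalancedMatrix) -> np.ndarray:
    """Mean balanced contact per genomic distance over unmasked pairs.

    Returns expected[d] for d = 0..n_bins-1, NaN where no unmasked pair
    exists at that distance.
    """
    n = bm.n_bins
    valid = np.outer(bm.mask, bm.mask)
    expected = np.full(n, np.nan)
    for d in range(n):
        vals = np.diagonal(bm.balanced, offset=d)
        ok = np.diagonal(valid, offset=d)
        if ok.any():
            expected[d] = vals[ok].mean()
    return expected


def observed_over_expected(bm: BalancedMatrix) -> OEMatrix:
    """Divide the balanced matrix per-diagonal by its expected value."""
    n = bm.n_bins
    expected = expected_profile(bm)
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = bm.balanced / expected[dist]
    valid = np.outer(bm.mask, bm.mask)
    oe[~valid] = np.nan
    return OEMatrix(chrom=bm.chrom, bin_size=bm.bin_size, oe=oe, expected=expected, mask=bm.mask)
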