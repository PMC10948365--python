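"""Plain-text readers/writers: FASTA, BED, bedGraph, COO matrices, ibed, probes.

All coordinates on disk follow each format's native convention (BED and
bedGraph are 0-based half-open, matching the package's internal
convention). Writers and readers are mutual inverses byte-for-byte for
files the writers produced.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .capture import IBED_COLUMNS
from .matrix import ContactMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_coo_matrix",
    "write_coo_matrix",
    "read_ibed",
    "write_ibed",
    "read_probe_table",
    "write_probe_table",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | Path, genome: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names) :])
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "value"]
    return df


def write_bedgraph(path: str | Path, df: pd.DataFrame, value_col: str = "value") -> None:
    out = df[["chrom", "start", "end", value_col]]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_coo_matrix(path: str | Path, cm: ContactMatrix) -> None:
    """Upper-triangle COO text: bin1<TAB>bin2<TAB>count, plus a header line
    recording chrom, bin size and bin count."""
    m = cm.matrix
    iu = np.triu_indices(cm.n_bins)
    vals = m[iu]
    nz = vals > 0
    with open(path, "w") as fh:
        fh.write(f"#chrom={cm.chrom}\tbin_size={cm.bin_size}\tn_bins={cm.n_bins}\n")
        for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{v:g}\n")


def read_coo_matrix(path: str | Path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#chrom="):
        raise ValueError(f"{path}: missing COO header line")
    fields = dict(kv.split("=", 1) for kv in header[1:].split("\t"))
    chrom = fields["chrom"]
    bin_size = int(fields["bin_size"])
    n = int(fields["n_bins"])
    data = pd.read_csv(path, sep="\t", comment="#", header=None, names=["i", "j", "count"])
    m = np.zeros((n, n))
    i = data["i"].to_numpy(dtype=int)
    j = data["j"].to_numpy(dtype=int)
    v = data["count"].to_numpy(dtype=float)
    m[i, j] = v
    low = np.tril_indices(n, k=-1)
    m[low] = m.T[low]
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=m, mask=m.sum(axis=0) > 0)


def write_ibed(path: str | Path, df: pd.DataFrame) -> None:
    df[IBED_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ibed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in IBED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ibed columns {missing}")
    return df


def write_probe_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.8g")


def read_probe_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
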