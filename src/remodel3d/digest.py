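"""In-silico restriction digestion and promoter-capture bait design.

A dual-enzyme Hi-C protocol (Arima-style) cuts at ``^GATC`` and ``G^ANTC``.
This module digests a genome with arbitrary IUPAC motifs, maps transcription
start sites (TSSs) onto the resulting fragment tiling, and builds capture
bait target regions: for each TSS the containing fragment plus one fragment
up- and downstream is selected; fragments longer than ``max_plain_len``
(700 bp) contribute only the two ``edge_len`` (350 bp) inward-facing edges,
shorter fragments are targeted whole.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RestrictionMotif",
    "DEFAULT_MOTIFS",
    "FragmentMap",
    "BaitSet",
    "digest_genome",
    "map_tss_to_fragments",
    "design_baits",
    "bait_stats",
    "tss_from_annotation",
]

# IUPAC degeneracy table. A genome letter matches a motif letter only if it
# is one of A/C/G/T and a member of the motif letter's set: assembly-gap Ns
# in the genome never match anything, including motif N.
_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class RestrictionMotif:
    """A restriction recognition motif with its cut position.

    ``cut_offset`` is the 0-based offset within a forward-strand match where
    the enzyme cuts, e.g. ``GATC`` with offset 0 is ``^GATC`` and ``GANTC``
    with offset 1 is ``G^ANTC``.
    """

    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("motif pattern is empty")
        bad = set(pat) - set(_IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in motif {self.pattern!r}")
        if not (0 <= self.cut_offset <= len(pat)):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside motif {self.pattern!r} of length {len(pat)}"
            )
        object.__setattr__(self, "pattern", pat)

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)

    def to_regex(self) -> re.Pattern[str]:
        # lookahead so overlapping occurrences are all reported
        body = "".join("[" + "".join(sorted(_IUPAC[c])) + "]" for c in self.pattern)
        return re.compile(f"(?=({body}))")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


#: The dual Arima motifs: ^GATC (DpnII) and G^ANTC (Arima's second enzyme).
DEFAULT_MOTIFS: tuple[RestrictionMotif, RestrictionMotif] = (
    RestrictionMotif("GATC", 0),
    RestrictionMotif("GANTC", 1),
)


@dataclass
class FragmentMap:
    """Ordered restriction-fragment tiling of each chromosome.

    ``fragments[chrom]`` is an (n, 2) int array of [start, end) intervals
    that exactly tile [0, chrom_length); fragment ids are row indices,
    consecutive within a chromosome.
    """

    chrom_lengths: dict[str, int]
    fragments: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, frags in self.fragments.items():
            length = self.chrom_lengths[chrom]
            if frags[0, 0] != 0 or frags[-1, 1] != length:
                raise ValueError(f"fragments do not tile chromosome {chrom}")
            if np.any(frags[1:, 0] != frags[:-1, 1]) or np.any(frags[:, 1] <= frags[:, 0]):
                raise ValueError(f"fragment tiling broken on chromosome {chrom}")

    def lengths(self, chrom: str | None = None) -> np.ndarray:
        if chrom is not None:
            f = self.fragments[chrom]
            return f[:, 1] - f[:, 0]
        return np.concatenate([f[:, 1] - f[:, 0] for f in self.fragments.values()])

    def n_fragments(self) -> int:
        return sum(len(f) for f in self.fragments.values())


@dataclass
class BaitRecord:
    tss_id: str
    chrom: str
    pos: int
    fragment_ids: list[int]  # containing fragment +/- 1, clipped at ends
    targets: list[tuple[int, int, int]]  # (start, end, source fragment id)
    span: int  # sum of selected fragment lengths


@dataclass
class BaitSet:
    """Per-TSS bait selections plus the de-duplicated union of target regions."""

    records: list[BaitRecord]
    union_targets: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (n,2)
    target_names: dict[str, list[str]] = field(default_factory=dict)  # comma-joined tss ids


def _cut_positions(seq: str, motif: RestrictionMotif) -> np.ndarray:
    cuts = [m.start() + motif.cut_offset for m in motif.to_regex().finditer(seq)]
    if not motif.is_palindromic:
        # scan the reverse-complement motif on the forward strand; a cut at
        # offset c from the 5' end of the motif maps to len - c on this strand
        rc = RestrictionMotif(reverse_complement(motif.pattern), len(motif.pattern) - motif.cut_offset)
        cuts.extend(m.start() + rc.cut_offset for m in rc.to_regex().finditer(seq))
    return np.asarray(cuts, dtype=np.int64)


def digest_genome(
    genome: Mapping[str, str],
    motifs: Sequence[RestrictionMotif] = DEFAULT_MOTIFS,
) -> FragmentMap:
    """Digest ``genome`` (name -> uppercase sequence) at every motif cut site.

    Cut positions are the union over motifs of (match start + cut offset)
    for every forward-strand match; overlapping matches all count and
    duplicate cut positions collapse. Fragments are the intervals between
    consecutive distinct cuts plus the chromosome ends.
    """
    if not genome:
        raise ValueError("empty genome")
    if not motifs:
        raise ValueError("no restriction motifs supplied")
    chrom_lengths: dict[str, int] = {}
    fragments: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom!r} is empty")
        seq = str(seq).upper()
        n = len(seq)
        cuts = np.concatenate([_cut_positions(seq, m) for m in motifs]) if motifs else np.array([])
        cuts = np.unique(cuts)
        cuts = cuts[(cuts > 0) & (cuts < n)]
        bounds = np.concatenate(([0], cuts, [n]))
        fragments[chrom] = np.column_stack((bounds[:-1], bounds[1:])).astype(np.int64)
        chrom_lengths[chrom] = n
    return FragmentMap(chrom_lengths=chrom_lengths, fragments=fragments)


def map_tss_to_fragments(
    fragment_map: FragmentMap,
    tss_table: Iterable[tuple[str, str, int]],
) -> dict[str, tuple[str, int]]:
    """Map each (tss_id, chrom, pos) to its containing fragment id.

    A TSS exactly at a cut site belongs to the fragment starting there
    (half-open convention). Returns tss_id -> (chrom, fragment id).
    """
    out: dict[str, tuple[str, int]] = {}
    for tss_id, chrom, pos in tss_table:
        if chrom not in fragment_map.fragments:
            raise KeyError(f"TSS {tss_id}: unknown chromosome {chrom!r}")
        length = fragment_map.chrom_lengths[chrom]
        if not (0 <= pos < length):
            raise ValueError(f"TSS {tss_id}: position {pos} outside chromosome {chrom} [0, {length})")
        starts = fragment_map.fragments[chrom][:, 0]
        idx = int(np.searchsorted(starts, pos, side="right") - 1)
        out[tss_id] = (chrom, idx)
    return out


def _fragment_targets(start: int, end: int, frag_id: int, max_plain_len: int, edge_len: int):
    if end - start <= max_plain_len:
        return [(start, end, frag_id)]
    return [(start, start + edge_len, frag_id), (end - edge_len, end, frag_id)]


def design_baits(
    fragment_map: FragmentMap,
    tss_map: Mapping[str, tuple[str, int]],
    tss_positions: Mapping[str, int] | None = None,
    max_plain_len: int = 700,
    edge_len: int = 350,
) -> BaitSet:
    """Build bait target regions for every mapped TSS.

    Selects the containing fragment plus one fragment on each side (clipped
    at chromosome ends), then applies the whole-fragment / two-edge rule per
    fragment. Fragments shared between TSSs appear once in the union output,
    with their TSS ids comma-joined.
    """
    if 2 * edge_len > max_plain_len:
        raise ValueError(
            f"edge_len {edge_len} x 2 exceeds max_plain_len {max_plain_len}: targets would overlap"
        )
    records: list[BaitRecord] = []
    # (chrom, frag id) -> contributing tss ids, preserving first-seen order
    frag_users: dict[tuple[str, int], list[str]] = {}
    for tss_id, (chrom, fid) in tss_map.items():
        frags = fragment_map.fragments[chrom]
        sel = [i for i in (fid - 1, fid, fid + 1) if 0 <= i < len(frags)]
        targets: list[tuple[int, int, int]] = []
        span = 0
        for i in sel:
            s, e = int(frags[i, 0]), int(frags[i, 1])
            span += e - s
            targets.extend(_fragment_targets(s, e, i, max_plain_len, edge_len))
            frag_users.setdefault((chrom, i), []).append(tss_id)
        pos = tss_positions[tss_id] if tss_positions is not None else -1
        records.append(BaitRecord(tss_id, chrom, pos, sel, targets, span))

    union_targets: dict[str, np.ndarray] = {}
    target_names: dict[str, list[str]] = {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for (chrom, fid), users in frag_users.items():
        s, e = fragment_map.fragments[chrom][fid]
        for ts, te, _ in _fragment_targets(int(s), int(e), fid, max_plain_len, edge_len):
            by_chrom.setdefault(chrom, []).append((ts, te, ",".join(users)))
    for chrom, rows in by_chrom.items():
        rows.sort()
        union_targets[chrom] = np.asarray([(s, e) for s, e, _ in rows], dtype=np.int64)
        target_names[chrom] = [name for _, _, name in rows]
    return BaitSet(records=records, union_targets=union_targets, target_names=target_names)


def bait_stats(bait_set: BaitSet) -> dict[str, float]:
    """Summary statistics over per-TSS spans and selected fragment lengths."""
    if not bait_set.records:
        raise ValueError("empty BaitSet")
    spans = np.asarray([r.span for r in bait_set.records], dtype=float)
    # individual selected fragment lengths, de-duplicated across TSSs
    seen: set[tuple[str, int, int]] = set()
    frag_lens: list[int] = []
    for r in bait_set.records:
        for s, e in _whole_fragments(r):
            key = (r.chrom, s, e)
            if key not in seen:
                seen.add(key)
                frag_lens.append(e - s)
    fl = np.asarray(frag_lens, dtype=float)
    return {
        "n_tss": len(bait_set.records),
        "span_mean": float(np.mean(spans)),
        "span_median": float(np.median(spans)),
        "span_min": float(np.min(spans)),
        "span_max": float(np.max(spans)),
        "fragment_mean": float(np.mean(fl)) if fl.size else float("nan"),
        "fragment_median": float(np.median(fl)) if fl.size else float("nan"),
    }


def _whole_fragments(record: BaitRecord) -> list[tuple[int, int]]:
    # reconstruct the selected fragments' [start, end) from the target list:
    # a fragment is either one whole-fragment target or two flush edge targets
    by_fid: dict[int, list[tuple[int, int]]] = {}
    for s, e, fid in record.targets:
        by_fid.setdefault(fid, []).append((s, e))
    out = []
    for fid, pieces in by_fid.items():
        out.append((min(s for s, _ in pieces), max(e for _, e in pieces)))
    return out


def tss_from_annotation(
    rows: Iterable[tuple[str, str, int, int, str]],
) -> list[tuple[str, str, int]]:
    """Strand-aware TSS extraction from (id, chrom, start, end, strand) rows.

    ``start``/``end`` are 0-based half-open transcript bounds; the TSS is
    ``start`` on the + strand and ``end - 1`` on the - strand.
    """
    out = []
    for tid, chrom, start, end, strand in rows:
        if strand == "-":
            out.append((tid, chrom, end - 1))
        else:
            out.append((tid, chrom, start))
    return out
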