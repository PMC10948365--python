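"""Synthetic two-condition remodeling scenarios with planted ground truth.

Emulates the data structures of a decitabine-style 3D-epigenome study on a
toy genome: replicated intra-chromosomal contact matrices with planted
compartment flips and weakened TAD boundaries, promoter-capture score
tables with planted one-to-many enhancer gains across a
control / treated / recovery time-course, and methylation probe tables
with planted enhancer hypomethylation and partial re-methylation. Every
generator is deterministic under the scenario seed and writes its truth in
machine-readable form next to the data.

The default scenario is desk-scale: one 20 Mb chromosome, 50 kb
compartment bins and 20 kb insulation bins, 3 replicates per condition at
5x10^5 pairs each, 500 baits. These sizes keep a full pipeline run within
minutes while leaving every planted signal statistically recoverable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ContactMatrix

__all__ = [
    "RemodelScenario",
    "compartment_scenario",
    "boundary_scenario",
    "null_scenario",
    "gen_genome_and_annotations",
    "gen_hic_pair",
    "gen_capture_tables",
    "gen_methylation_tables",
    "simulate_all",
]

# fixed per-stage entropy offsets so stages are individually reproducible
_STAGE_KEY = {"genome": 11, "hic": 23, "capture": 37, "methylation": 53}


@dataclass
class RemodelScenario:
    """All knobs of a planted two-condition remodeling experiment."""

    seed: int = 0
    chrom_name: str = "chr1"
    chrom_length: int = 20_000_000
    # compartments: alternating A/B blocks; a subset of B blocks flips to A
    # in condition 2 (the direction dominating hypomethylation-induced
    # remodeling), plus optionally A blocks flipping to B
    compartment_bin: int = 50_000
    block_size: int = 500_000
    n_flip_b_to_a: int = 8
    n_flip_a_to_b: int = 2
    gamma: float = 0.5  # within- vs between-compartment contact affinity
    decay_alpha: float = 1.0  # distance-decay exponent
    depth: int = 500_000  # expected pairs per replicate
    n_replicates: int = 3
    # TAD boundaries at the insulation resolution
    insulation_bin: int = 20_000
    n_boundaries: int = 20
    boundary_attenuation: float = 0.2
    n_weakened: int = 10  # boundaries removed (attenuation -> 1) in cond 2
    # promoter-capture tables
    n_baits: int = 500
    lambda_base: float = 8.0  # true OE interactions per bait
    lambda_gain: float = 3.0  # planted treated-stage gains per bait
    noise_rate: float = 3.0  # sub-threshold noise records per bait/replicate
    score_exp_mean: float = 4.0  # score = 5 + Exp(mean)
    score_jitter_sd: float = 0.5
    rho_loss: float = 0.734  # P(planted gain lost at recovery)
    bait_to_bait_frac: float = 0.02
    # methylation probes
    n_probes: int = 20_000
    beta_a: float = 8.0
    beta_b: float = 2.0
    delta_beta: float = 0.4
    recovery_regain: float = 0.5  # fraction of delta regained at recovery
    full_remeth_frac: float = 0.4  # enhancers fully re-methylated at recovery
    beta_noise_sd: float = 0.03
    n_meth_replicates: int = 4
    detp_masked_frac: float = 0.01
    n_enhancers: int = 40
    enhancer_size: int = 5_000

    def __post_init__(self) -> None:
        if self.decay_alpha <= 0:
            raise ValueError("decay exponent must be positive")
        if min(self.lambda_base, self.lambda_gain, self.noise_rate) < 0:
            raise ValueError("capture rates must be non-negative")
        if self.block_size % self.compartment_bin:
            raise ValueError("block size must be a multiple of the compartment bin")
        if self.n_blocks * self.block_size > self.chrom_length:
            raise ValueError("compartment blocks exceed the chromosome")

    @property
    def n_blocks(self) -> int:
        return self.chrom_length // self.block_size

    def rng(self, stage: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE_KEY[stage], extra])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RemodelScenario":
        return cls(**json.loads(Path(path).read_text()))

    # ---- planted truth ------------------------------------------------

    def block_labels(self, condition: int) -> np.ndarray:
        """Per-block 'A'/'B' labels; condition 2 applies the planted flips."""
        labels = np.array(["A" if i % 2 == 0 else "B" for i in range(self.n_blocks)], dtype=object)
        if condition == 2:
            b_blocks = [i for i in range(self.n_blocks) if i % 2 == 1]
            a_blocks = [i for i in range(self.n_blocks) if i % 2 == 0]
            rng = self.rng("hic", extra=999)
            flip_b = rng.choice(b_blocks, size=min(self.n_flip_b_to_a, len(b_blocks)), replace=False)
            flip_a = rng.choice(a_blocks, size=min(self.n_flip_a_to_b, len(a_blocks)), replace=False)
            labels[flip_b] = "A"
            labels[flip_a] = "B"
        return labels

    def bin_labels(self, condition: int, bin_size: int) -> np.ndarray:
        blocks = self.block_labels(condition)
        n_bins = int(np.ceil(self.chrom_length / bin_size))
        pos = (np.arange(n_bins) * bin_size + bin_size // 2)
        block_idx = np.minimum(pos // self.block_size, self.n_blocks - 1)
        return blocks[block_idx]

    def boundary_positions(self) -> np.ndarray:
        """Planted boundary positions (bp), evenly spread, jittered once."""
        rng = self.rng("hic", extra=777)
        spacing = self.chrom_length // (self.n_boundaries + 1)
        pos = (np.arange(1, self.n_boundaries + 1) * spacing).astype(np.int64)
        pos += rng.integers(-spacing // 4, spacing // 4, size=self.n_boundaries)
        return np.sort(pos)

    def boundary_attenuations(self, condition: int) -> np.ndarray:
        att = np.full(self.n_boundaries, self.boundary_attenuation)
        if condition == 2:
            rng = self.rng("hic", extra=778)
            weak = rng.choice(self.n_boundaries, size=min(self.n_weakened, self.n_boundaries), replace=False)
            att[np.sort(weak)] = 1.0
        return att


def compartment_scenario(seed: int = 0, n_flips: int = 30) -> RemodelScenario:
    """Compartment-focused scenario: a 40 Mb chromosome of 80 alternating
    500 kb blocks with ``n_flips`` planted B->A switches (plus two A->B) and
    no planted TAD boundaries, so the flip signal is the only structure
    beyond distance decay."""
    return RemodelScenario(
        seed=seed,
        chrom_length=40_000_000,
        n_flip_b_to_a=n_flips,
        n_flip_a_to_b=2,
        n_boundaries=0,
        n_weakened=0,
    )


def boundary_scenario(seed: int = 0) -> RemodelScenario:
    """Insulation-focused scenario: planted boundaries on a flat compartment
    background (gamma = 0), since compartment-block junctions are themselves
    genuine insulation dips and would confound boundary precision."""
    return RemodelScenario(
        seed=seed,
        gamma=0.0,
        n_flip_b_to_a=0,
        n_flip_a_to_b=0,
    )


def null_scenario(seed: int = 0) -> RemodelScenario:
    """Both conditions generated from identical parameters (no planted
    flips, no boundary weakening): every switch call is a false positive."""
    return RemodelScenario(
        seed=seed,
        n_flip_b_to_a=0,
        n_flip_a_to_b=0,
        n_boundaries=0,
        n_weakened=0,
    )


# ---------------------------------------------------------------------------
# genome + annotations


def gen_genome_and_annotations(scenario: RemodelScenario) -> dict:
    """Random A/C/G/T genome, TSS table, chromatin-state BED, gene density.

    TSSs sit inside promoter-state intervals placed in A blocks; per-bin
    gene density is higher in A blocks so eigenvector orientation is
    testable. Enhancer-state intervals double as the methylation truth.
    """
    rng = scenario.rng("genome")
    seq = rng.integers(0, 4, size=scenario.chrom_length, dtype=np.uint8)
    genome = {scenario.chrom_name: bytes(np.array([65, 67, 71, 84], dtype=np.uint8)[seq]).decode()}

    labels = scenario.block_labels(condition=1)
    a_blocks = np.where(labels == "A")[0]
    # promoters: a few per A block, each 2 kb; TSS at the promoter midpoint
    promoters = []
    tss_rows = []
    tid = 0
    for blk in a_blocks:
        base = blk * scenario.block_size
        for _ in range(3):
            start = int(base + rng.integers(0, scenario.block_size - 2000))
            promoters.append((scenario.chrom_name, start, start + 2000, "promoter"))
            tss_rows.append((f"tss{tid}", scenario.chrom_name, start + 1000))
            tid += 1
    # enhancers: fixed-size intervals, anywhere outside promoters
    enhancers = []
    for k in range(scenario.n_enhancers):
        start = int(rng.integers(0, scenario.chrom_length - scenario.enhancer_size))
        enhancers.append((scenario.chrom_name, start, start + scenario.enhancer_size, "enhancer"))
    states = pd.DataFrame(
        sorted(promoters + enhancers, key=lambda r: r[1]),
        columns=["chrom", "start", "end", "name"],
    )

    n_bins = int(np.ceil(scenario.chrom_length / scenario.compartment_bin))
    gene_density = np.where(
        scenario.bin_labels(1, scenario.compartment_bin) == "A", 5.0, 1.0
    ) + rng.normal(0, 0.2, n_bins)

    return {
        "genome": genome,
        "tss": pd.DataFrame(tss_rows, columns=["tss_id", "chrom", "pos"]),
        "states": states,
        "gene_density": gene_density,
        "truth": {
            "a_blocks": a_blocks.tolist(),
            "enhancers": [list(e[:3]) for e in enhancers],
        },
    }


# ---------------------------------------------------------------------------
# Hi-C


def _expected_matrix(scenario: RemodelScenario, condition: int, bin_size: int) -> np.ndarray:
    n = int(np.ceil(scenario.chrom_length / bin_size))
    labels = scenario.bin_labels(condition, bin_size)
    same = (labels[:, None] == labels[None, :])
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    e = (1.0 + dist) ** (-scenario.decay_alpha)
    e *= np.where(same, 1.0 + scenario.gamma, 1.0 - scenario.gamma)
    # boundary attenuation: multiply for each planted boundary strictly
    # between the two bins, at most 2 crossings counted
    atts = scenario.boundary_attenuations(condition)
    mid = idx * bin_size + bin_size // 2
    bcuts = scenario.boundary_positions()
    # crossing count matrix via searchsorted on bin midpoints
    rank = np.searchsorted(bcuts, mid)
    for b, (cut, att) in enumerate(zip(bcuts, atts)):
        if att >= 1.0:
            continue
        left = rank <= b  # bins before this boundary
        crosses = np.logical_xor(left[:, None], left[None, :])
        e = np.where(crosses, e * att, e)
    # cap the total attenuation at two crossings' worth
    n_cross = np.abs(rank[:, None] - rank[None, :])
    att_floor = scenario.boundary_attenuation ** 2
    base = (1.0 + dist) ** (-scenario.decay_alpha) * np.where(
        same, 1.0 + scenario.gamma, 1.0 - scenario.gamma
    )
    e = np.maximum(e, base * att_floor)
    # scale so the expected upper-triangle total equals the depth
    iu = np.triu_indices(n)
    e *= scenario.depth / e[iu].sum()
    return e


def gen_hic_pair(scenario: RemodelScenario, bin_size: int | None = None) -> dict:
    """Replicated Poisson contact matrices for both conditions plus truth."""
    bin_size = bin_size or scenario.insulation_bin
    out: dict = {"condition1": [], "condition2": []}
    for cond, key in ((1, "condition1"), (2, "condition2")):
        e = _expected_matrix(scenario, cond, bin_size)
        for rep in range(scenario.n_replicates):
            rng = scenario.rng("hic", extra=cond * 100 + rep)
            iu = np.triu_indices(e.shape[0])
            counts = np.zeros_like(e)
            counts[iu] = rng.poisson(e[iu])
            counts = counts + np.triu(counts, k=1).T
            out[key].append(
                ContactMatrix(
                    chrom=scenario.chrom_name,
                    bin_size=bin_size,
                    matrix=counts,
                    mask=counts.sum(axis=0) > 0,
                )
            )
    lab1 = scenario.bin_labels(1, bin_size)
    lab2 = scenario.bin_labels(2, bin_size)
    out["truth"] = {
        "bin_size": bin_size,
        "labels_cond1": lab1.tolist(),
        "labels_cond2": lab2.tolist(),
        "switched_bins": np.where(lab1 != lab2)[0].tolist(),
        "boundary_bins": (scenario.boundary_positions() // bin_size).tolist(),
        "boundary_attenuation_cond1": scenario.boundary_attenuations(1).tolist(),
        "boundary_attenuation_cond2": scenario.boundary_attenuations(2).tolist(),
    }
    return out


# ---------------------------------------------------------------------------
# promoter capture


def _draw_score(rng: np.random.Generator, n: int, scenario: RemodelScenario) -> np.ndarray:
    return 5.0 + rng.exponential(scenario.score_exp_mean, size=n)


def gen_capture_tables(scenario: RemodelScenario) -> dict:
    """ibed-like tables for control / treated / recovery stages plus truth.

    True interactions score 5 + Exp(mean 4) with per-replicate Normal(0,
    0.5) jitter truncated at 0; noise records score Uniform(0, 5); planted
    gains exist from the treated stage on and survive into recovery with
    probability 1 - rho_loss. A small fraction of records is emitted
    bait-to-bait (other end named like a bait) to exercise filtering.
    """
    rng = scenario.rng("capture")
    anchor = 5_000  # anchor width and grid
    n_slots = scenario.chrom_length // anchor
    bait_slots = rng.choice(n_slots, size=scenario.n_baits, replace=False)
    bait_slots.sort()

    bait_set = set(int(s) for s in bait_slots)
    # other ends already used per bait, so distinct planted interactions
    # stay > merge-gap apart and map 1:1 onto merged regions
    used_oe: dict[int, set[int]] = {int(s): set() for s in bait_slots}

    def draw_oe(slot: int, r: np.random.Generator, reserve: bool = False) -> int:
        # keep other ends off bait fragments; bait-to-bait records are
        # emitted separately so planted truth survives the filter
        taken = used_oe[slot] if reserve else set()
        while True:
            off = int(r.integers(1, 200)) * (1 if r.random() < 0.5 else -1)
            oe_slot = int(np.clip(slot + off, 0, n_slots - 1))
            if oe_slot in bait_set:
                continue
            if reserve and any(abs(oe_slot - u) <= 3 for u in taken):
                continue
            if reserve:
                used_oe[slot].add(oe_slot)
            return oe_slot

    def new_interactions(rate: float, tag: str) -> list[dict]:
        rows = []
        for b, slot in enumerate(bait_slots):
            k = rng.poisson(rate)
            for _ in range(k):
                oe_slot = draw_oe(int(slot), rng, reserve=True)
                rows.append(
                    {
                        "bait": int(slot),
                        "oe": oe_slot,
                        "base_score": float(_draw_score(rng, 1, scenario)[0]),
                        "kind": tag,
                    }
                )
        return rows

    base = new_interactions(scenario.lambda_base, "base")
    gains = new_interactions(scenario.lambda_gain, "gain")
    lost_flags = rng.random(len(gains)) < scenario.rho_loss
    for g, lost in zip(gains, lost_flags):
        g["timecourse_class"] = "gained_and_lost" if lost else "gained_and_maintained"

    stages = {
        "control": base,
        "treated": base + gains,
        "recovery": base + [g for g, lost in zip(gains, lost_flags) if not lost],
    }
    chrom = scenario.chrom_name
    stage_key = {"control": 1, "treated": 2, "recovery": 3}
    tables: dict[str, list[pd.DataFrame]] = {}
    for stage, interactions in stages.items():
        tables[stage] = []
        for rep in range(scenario.n_replicates):
            rrng = scenario.rng("capture", extra=stage_key[stage] * 100 + rep + 1)
            rows = []
            for it in interactions:
                score = max(0.0, it["base_score"] + rrng.normal(0, scenario.score_jitter_sd))
                rows.append(_ibed_row(chrom, it["bait"], it["oe"], anchor, score))
            # sub-threshold noise records, plus bait-to-bait records that the
            # filter step must remove
            for slot in bait_slots:
                for _ in range(rrng.poisson(scenario.noise_rate)):
                    oe_slot = draw_oe(int(slot), rrng)
                    rows.append(_ibed_row(chrom, slot, oe_slot, anchor, float(rrng.uniform(0, 5))))
                if rrng.random() < scenario.bait_to_bait_frac * 10:
                    other = int(bait_slots[rrng.integers(len(bait_slots))])
                    rows.append(
                        _ibed_row(chrom, slot, other, anchor, float(_draw_score(rrng, 1, scenario)[0]), b2b=True)
                    )
            df = pd.DataFrame(rows)
            tables[stage].append(df.sort_values(["bait_start", "oe_start"]).reset_index(drop=True))

    truth = {
        "bait_slots": bait_slots.tolist(),
        "anchor": anchor,
        "planted_gains": [
            {
                "bait": g["bait"],
                "oe": g["oe"],
                "timecourse_class": g["timecourse_class"],
            }
            for g in gains
        ],
        "n_gained_and_lost": int(lost_flags.sum()),
        "n_gains": len(gains),
    }
    return {"tables": tables, "truth": truth}


def _ibed_row(chrom, bait_slot, oe_slot, anchor, score, b2b: bool = False) -> dict:
    return {
        "bait_chr": chrom,
        "bait_start": int(bait_slot) * anchor,
        "bait_end": (int(bait_slot) + 1) * anchor,
        "bait_name": f"bait{int(bait_slot)}",
        "oe_chr": chrom,
        "oe_start": int(oe_slot) * anchor,
        "oe_end": (int(oe_slot) + 1) * anchor,
        "oe_name": f"bait{int(oe_slot)}" if b2b else ".",
        "N_reads": int(max(1, round(score))),
        "score": round(float(score), 4),
    }


# ---------------------------------------------------------------------------
# methylation


def gen_methylation_tables(scenario: RemodelScenario, enhancers: list[list] | None = None) -> dict:
    """Probe tables for control (early/late), treated and recovery groups.

    Baseline beta ~ Beta(a, b) per probe; treated subtracts delta_beta at
    probes inside enhancer truth intervals (plus Normal noise, clipped to
    [0, 1)); recovery adds back recovery_regain * delta_beta, or the full
    delta for the fully re-methylated enhancer subset. M/U intensities are
    back-computed so beta = M / (U + M + 100) holds exactly.
    """
    rng = scenario.rng("methylation")
    if enhancers is None:
        enhancers = gen_genome_and_annotations(scenario)["truth"]["enhancers"]
    # EPIC-style design: probes enriched at regulatory regions — a dense
    # ladder (400 bp spacing) inside each enhancer, uniform background
    # elsewhere, so the <= 1 kb chaining rule can operate inside truth blocks
    dense = [
        np.arange(s + 200, e - 100, 400, dtype=np.int64) for _c, s, e in enhancers
    ]
    dense_pos = np.concatenate(dense) if dense else np.array([], dtype=np.int64)
    n_bg = max(scenario.n_probes - dense_pos.size, 0)
    bg = rng.choice(scenario.chrom_length, size=n_bg, replace=False)
    pos = np.unique(np.concatenate([dense_pos, bg]))
    n = pos.size
    baseline = rng.beta(scenario.beta_a, scenario.beta_b, size=n)

    in_enh = np.zeros(n, dtype=bool)
    enh_idx = np.full(n, -1)
    for k, (_c, s, e) in enumerate(enhancers):
        sel = (pos >= s) & (pos < e)
        in_enh |= sel
        enh_idx[sel] = k
    full_remeth = rng.random(len(enhancers)) < scenario.full_remeth_frac

    regain = np.zeros(n)
    regain[in_enh] = scenario.recovery_regain * scenario.delta_beta
    for k in np.where(full_remeth)[0]:
        regain[enh_idx == k] = scenario.delta_beta

    group_means = {
        "control_early": baseline,
        "control_late": baseline,
        "treated": np.where(in_enh, baseline - scenario.delta_beta, baseline),
        "recovery": np.where(in_enh, baseline - scenario.delta_beta + regain, baseline),
    }
    table = pd.DataFrame(
        {
            "probe": [f"cg{i:07d}" for i in range(n)],
            "chrom": scenario.chrom_name,
            "pos": pos,
        }
    )
    samples: dict[str, list[str]] = {}
    for g, (gname, mean) in enumerate(group_means.items()):
        samples[gname] = []
        for rep in range(scenario.n_meth_replicates):
            srng = scenario.rng("methylation", extra=1 + g * 10 + rep)
            beta = np.clip(mean + srng.normal(0, scenario.beta_noise_sd, n), 0.0, 1 - 1e-9)
            total = srng.lognormal(np.log(5000.0), 0.3, n)
            total = np.maximum(total, 100.0 * beta / np.maximum(1 - beta, 1e-12) + 1)
            meth = beta * (total + 100.0)
            unmeth = total - meth
            detp = np.where(srng.random(n) < scenario.detp_masked_frac, 0.02, 0.0)
            sample = f"{gname}_{rep + 1}"
            samples[gname].append(sample)
            table[f"{sample}_M"] = meth
            table[f"{sample}_U"] = unmeth
            table[f"{sample}_detP"] = detp
    truth = {
        "enhancers": [list(e) for e in enhancers],
        "fully_remethylated": [list(enhancers[k]) for k in np.where(full_remeth)[0]],
        "delta_beta": scenario.delta_beta,
    }
    return {"table": table, "samples": samples, "truth": truth}


# ---------------------------------------------------------------------------
# one-call orchestration


def simulate_all(scenario: RemodelScenario, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic data product and truth file under ``outdir``."""
    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    scenario.to_json(outdir / "scenario.json")
    paths["scenario"] = outdir / "scenario.json"

    g = gen_genome_and_annotations(scenario)
    rio.write_fasta(outdir / "genome.fa", g["genome"])
    g["tss"].to_csv(outdir / "tss.tsv", sep="\t", index=False)
    rio.write_bed(outdir / "states.bed", g["states"])
    bs = scenario.compartment_bin
    gd = pd.DataFrame(
        {
            "chrom": scenario.chrom_name,
            "start": np.arange(len(g["gene_density"])) * bs,
            "end": (np.arange(len(g["gene_density"])) + 1) * bs,
            "value": g["gene_density"],
        }
    )
    rio.write_bedgraph(outdir / "gene_density.bedgraph", gd)
    paths["genome"] = outdir / "genome.fa"

    for bin_size, tag in ((scenario.compartment_bin, "compartment"), (scenario.insulation_bin, "insulation")):
        hic = gen_hic_pair(scenario, bin_size=bin_size)
        for key in ("condition1", "condition2"):
            for rep, cm in enumerate(hic[key]):
                p = outdir / f"hic_{tag}_{key}_rep{rep + 1}.coo"
                rio.write_coo_matrix(p, cm)
        (outdir / f"hic_{tag}_truth.json").write_text(json.dumps(hic["truth"], indent=1) + "\n")

    cap = gen_capture_tables(scenario)
    for stage, reps in cap["tables"].items():
        for rep, df in enumerate(reps):
            rio.write_ibed(outdir / f"capture_{stage}_rep{rep + 1}.ibed", df)
    (outdir / "capture_truth.json").write_text(json.dumps(cap["truth"], indent=1) + "\n")

    meth = gen_methylation_tables(scenario, enhancers=g["truth"]["enhancers"])
    rio.write_probe_table(outdir / "methylation.csv", meth["table"])
    (outdir / "methylation_samples.json").write_text(json.dumps(meth["samples"], indent=1) + "\n")
    (outdir / "methylation_truth.json").write_text(json.dumps(meth["truth"], indent=1) + "\n")
    paths["outdir"] = outdir
    return paths
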