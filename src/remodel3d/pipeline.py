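"""End-to-end two-condition remodeling pipeline and consolidated report.

Consumes a directory of inputs (as produced by
:func:`remodel3d.synthetic.simulate_all`, or equivalently-shaped user
files), runs each analysis section in dependency order — balancing ->
O/E -> compartments/saddle, insulation -> boundaries -> differential,
capture filter -> differential -> connectivity -> time-course, beta ->
DMRs -> enrichment — and writes a single JSON report whose percentages are
re-derived from their own counts at write time. Sections are isolated: a
failure in one is recorded without corrupting the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import capture as cap
from . import compartments as comp
from . import insulation as ins
from . import intervals as iv
from . import io as rio
from . import matrix as mx
from . import methylation as meth

log = logging.getLogger("remodel3d")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All thresholds of a run; defaults follow the study's printed values."""

    input_dir: str
    output_dir: str
    seed: int = 0
    # contact matrices
    ice_tol: float = 1e-5
    ice_max_iter: int = 200
    mask_low_frac: float = 0.02
    # compartments
    min_rep_agree: float = 1.0
    saddle_quantiles: int = 20
    corner_frac: float = 0.2
    # insulation / TADs
    window_bp: int = 102_353
    insulation_cutoff: float = 50.0
    # capture interactions
    score_min: float = 5.0
    k_of_n: int = 2
    asinh_delta: float = 1.0
    merge_gap: int = 10_000
    # methylation
    dmr_max_gap: int = 1000
    dmr_min_probes: int = 2
    dmr_min_delta: float = 0.30
    remethylation_delta: float = 0.30
    # enrichment
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def sub_seed(self, stage: str) -> int:
        # stable per-stage sub-seed below 2**31
        h = sum((i + 1) * ord(c) for i, c in enumerate(stage))
        return (self.seed * 10_007 + h) % (2**31 - 1)


def _load_replicate_matrices(indir: Path, tag: str, cond: str) -> list[mx.ContactMatrix]:
    paths = sorted(indir.glob(f"hic_{tag}_{cond}_rep*.coo"))
    if not paths:
        raise FileNotFoundError(f"no contact matrices matching hic_{tag}_{cond}_rep*.coo in {indir}")
    return [rio.read_coo_matrix(p) for p in paths]


def _section_compartments(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    gd = rio.read_bedgraph(indir / "gene_density.bedgraph")["value"].to_numpy()
    tracks: dict[str, list[comp.CompartmentTrack]] = {}
    oes: dict[str, mx.OEMatrix] = {}
    for cond in ("condition1", "condition2"):
        tracks[cond] = []
        mats = _load_replicate_matrices(indir, "compartment", cond)
        for cm in mats:
            bm = mx.ice_balance(cm, max_iter=cfg.ice_max_iter, tol=cfg.ice_tol, mask_low_frac=cfg.mask_low_frac)
            oe = mx.observed_over_expected(bm)
            tracks[cond].append(comp.compute_pc1(oe, gd))
        merged = mx.merge_matrices(mats)
        bm = mx.ice_balance(merged, max_iter=cfg.ice_max_iter, tol=cfg.ice_tol, mask_low_frac=cfg.mask_low_frac)
        oes[cond] = mx.observed_over_expected(bm)

    switches = comp.classify_switches(tracks["condition1"], tracks["condition2"], cfg.min_rep_agree)
    switches.to_csv(outdir / "compartment_switches.tsv", sep="\t", index=False)
    summary = comp.switch_summary(switches)
    strengths = {}
    for cond in ("condition1", "condition2"):
        merged_track = comp.compute_pc1(oes[cond], gd)
        sad = comp.saddle_strength(
            oes[cond], merged_track, n_quantiles=cfg.saddle_quantiles, corner_frac=cfg.corner_frac
        )
        strengths[cond] = sad.strength
        np.savetxt(outdir / f"saddle_{cond}.tsv", sad.saddle, delimiter="\t")
    summary["saddle_strength_cond1"] = strengths["condition1"]
    summary["saddle_strength_cond2"] = strengths["condition2"]
    return summary


def _section_tads(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    reps: dict[str, list[list[ins.Boundary]]] = {}
    chrom = None
    bin_size = None
    tad_counts = {}
    for cond in ("condition1", "condition2"):
        reps[cond] = []
        n_tads = []
        for cm in _load_replicate_matrices(indir, "insulation", cond):
            chrom, bin_size = cm.chrom, cm.bin_size
            bm = mx.ice_balance(cm, max_iter=cfg.ice_max_iter, tol=cfg.ice_tol, mask_low_frac=cfg.mask_low_frac)
            track = ins.insulation_track(bm, window_bp=cfg.window_bp)
            boundaries, tads = ins.call_boundaries_and_tads(track, cutoff=cfg.insulation_cutoff)
            reps[cond].append(boundaries)
            n_tads.append(len(tads))
        tad_counts[cond] = float(np.mean(n_tads))
    diff = ins.reconcile_boundaries(reps["condition1"], reps["condition2"], chrom, bin_size)
    diff.to_csv(outdir / "boundary_differential.tsv", sep="\t", index=False)
    counts = diff["status"].value_counts().to_dict()
    return {
        "mean_n_tads_cond1": tad_counts["condition1"],
        "mean_n_tads_cond2": tad_counts["condition2"],
        "n_common_boundaries": int(counts.get("common", 0)),
        "n_cond1_specific": int(counts.get("cond1_specific", 0)),
        "n_cond2_specific": int(counts.get("cond2_specific", 0)),
    }


def _load_capture_stage(indir: Path, stage: str, score_min: float) -> list[pd.DataFrame]:
    paths = sorted(indir.glob(f"capture_{stage}_rep*.ibed"))
    if not paths:
        raise FileNotFoundError(f"no capture tables for stage {stage} in {indir}")
    return [cap.load_and_filter(rio.read_ibed(p), score_min)[0] for p in paths]


def _section_capture(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    control = _load_capture_stage(indir, "control", cfg.score_min)
    treated = _load_capture_stage(indir, "treated", cfg.score_min)
    calls = cap.consensus_and_diff(
        control, treated, k_of_n=cfg.k_of_n, score_min=cfg.score_min,
        asinh_delta=cfg.asinh_delta, merge_gap=cfg.merge_gap,
    )
    calls.to_csv(outdir / "capture_differential.tsv", sep="\t", index=False)
    per_bait, conn = cap.per_bait_connectivity(calls)
    per_bait.to_csv(outdir / "capture_connectivity.tsv", sep="\t", index=False)
    out = {
        "n_gained": int((calls["class"] == "gained").sum()),
        "n_lost": int((calls["class"] == "lost").sum()),
        "n_maintained": int((calls["class"] == "maintained").sum()),
        **conn,
    }
    recovery_paths = sorted(indir.glob("capture_recovery_rep*.ibed"))
    if recovery_paths:
        recovery = _load_capture_stage(indir, "recovery", cfg.score_min)
        rec_calls = cap.consensus_and_diff(
            control, recovery, k_of_n=cfg.k_of_n, score_min=cfg.score_min,
            asinh_delta=cfg.asinh_delta, merge_gap=cfg.merge_gap,
        )
        rec_sig = rec_calls[rec_calls["cond2_significant"]]
        labelled, tc = cap.timecourse_partition(calls, rec_sig)
        labelled.to_csv(outdir / "capture_timecourse.tsv", sep="\t", index=False)
        out.update(tc)
    return out


def _section_methylation(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    table = rio.read_probe_table(indir / "methylation.csv")
    samples = json.loads((indir / "methylation_samples.json").read_text())
    all_samples = [s for group in samples.values() for s in group]
    beta = pd.DataFrame(
        {
            s: meth.beta_from_signals(
                table[f"{s}_M"].to_numpy(), table[f"{s}_U"].to_numpy(), table[f"{s}_detP"].to_numpy()
            )
            for s in all_samples
        }
    )
    control = samples.get("control_early", []) + samples.get("control_late", [])
    dmrs = meth.call_dmrs(
        table, beta, control, samples["treated"],
        max_gap=cfg.dmr_max_gap, min_probes=cfg.dmr_min_probes, min_delta=cfg.dmr_min_delta,
    )
    rio.write_bed(
        outdir / "dmrs.bed",
        dmrs.assign(name=dmrs["direction"], score=(dmrs["mean_delta"].abs() * 1000).round().astype(int)),
    )
    out = {
        "n_dmrs": int(len(dmrs)),
        "n_hypo": int((dmrs["direction"] == "hypo").sum()),
        "n_hyper": int((dmrs["direction"] == "hyper").sum()),
    }
    states = rio.read_bed(indir / "states.bed")
    enhancers = states[states["name"] == "enhancer"][["chrom", "start", "end"]]
    if "recovery" in samples and len(enhancers):
        summary = meth.region_methylation_summary(
            table, beta, enhancers,
            {"control": control, "treated": samples["treated"], "recovery": samples["recovery"]},
            remethylation_delta=cfg.remethylation_delta,
        )
        summary.to_csv(outdir / "enhancer_methylation.tsv", sep="\t", index=False)
        out["n_enhancers_scored"] = int(summary["n_probes"].gt(0).sum())
        out["n_remethylated"] = int(summary["remethylated"].sum())
    return out


def _section_enrichment(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    dmr_bed = outdir / "dmrs.bed"
    if not dmr_bed.exists():
        raise FileNotFoundError("DMR section output missing; enrichment skipped")
    dmrs = rio.read_bed(dmr_bed)
    states = rio.read_bed(indir / "states.bed")
    chrom_end = int(
        max(states["end"].max(), dmrs["end"].max() if len(dmrs) else 0) + 1_000_000
    )
    workspace = pd.DataFrame({"chrom": [states["chrom"].iloc[0]], "start": [0], "end": [chrom_end]})
    results = []
    for state_name in sorted(states["name"].unique()):
        ann = states[states["name"] == state_name][["chrom", "start", "end"]]
        res = iv.permutation_enrichment(
            dmrs[["chrom", "start", "end"]], ann, workspace,
            n_perm=cfg.n_permutations, seed=cfg.sub_seed(f"enrichment:{state_name}"),
            name=state_name,
        )
        results.append(res)
    qs = iv.bh_adjust([r.p_enriched for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    tab = pd.DataFrame(
        [
            {
                "annotation": r.annotation,
                "observed": r.observed,
                "expected_mean": r.perm_mean,
                "expected_sd": r.perm_sd,
                "fold": r.fold,
                "p": r.p_enriched,
                "q": r.q,
            }
            for r in results
        ]
    )
    tab.to_csv(outdir / "dmr_enrichment.tsv", sep="\t", index=False)
    return {r.annotation: {"fold": r.fold, "p": r.p_enriched, "q": r.q} for r in results}


def _check_consistency(report: dict) -> None:
    """Every reported percentage must be recomputable from its counts."""
    comp_sec = report.get("compartments", {})
    if "pct_activation" in comp_sec and np.isfinite(comp_sec["pct_activation"]):
        switching = comp_sec["n_A->B"] + comp_sec["n_B->A"]
        expect = 100.0 * comp_sec["n_B->A"] / switching
        assert abs(expect - comp_sec["pct_activation"]) < 1e-9, "switch percentage inconsistent"
    cap_sec = report.get("capture", {})
    if "pct_lost" in cap_sec:
        expect = 100.0 * cap_sec["n_gained_and_lost"] / cap_sec["n_gained"]
        assert abs(expect - cap_sec["pct_lost"]) < 1e-9, "time-course percentage inconsistent"


def run_pipeline(config: RunConfig) -> dict:
    """Run every section; returns (and writes) the consolidated report."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    if not indir.is_dir():
        raise FileNotFoundError(f"input directory {indir} does not exist")

    report: dict = {"config": asdict(config), "errors": {}}
    sections = {
        "compartments": _section_compartments,
        "tads": _section_tads,
        "capture": _section_capture,
        "methylation": _section_methylation,
        "enrichment": _section_enrichment,
    }
    for name, fn in sections.items():
        try:
            log.info("running section %s", name)
            report[name] = fn(config, indir, outdir)
        except Exception as exc:  # section isolation: record, keep going
            log.error("section %s failed: %s", name, exc)
            report["errors"][name] = str(exc)
    _check_consistency(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
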