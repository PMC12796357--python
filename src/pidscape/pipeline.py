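"""End-to-end orchestration: simulate -> background -> PIDs -> differential ->
annotate -> enrich, plus evaluation against the planted truth."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import background_model as bg
from . import cre_annotation as ann
from . import differential as diff
from . import pid_caller as pc
from . import synthetic_data as synth
from . import variant_enrichment as ve
from .contact_store import merge_replicates, scale_to_smallest, write_contacts
from .genome import intervals_overlap, write_bed

logger = logging.getLogger("pidscape")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults match the published analysis."""

    outdir: str = "pidscape_run"
    seed: int = 0
    # simulation
    n_genes: int = 50
    n_cres: int = 150
    n_loops: int = 30
    chrom_length: int = 10_000_000
    bin_size: int = 1000
    replicates_per_condition: int = 3
    target_depth: float = 500_000.0
    decay_exponent: float = 0.85
    nb_dispersion: float = 0.2
    base_enhancement: float = 3.0
    condition_factor_a: float = 1.0
    loop_distance: tuple = (14_000, 24_000)
    anchor_width: int = 10_000
    # analysis (published-protocol defaults)
    viewpoint_halfwidth: int = 2_500
    range_bp: int = 1_000_000
    avg_bins: int = 5
    fixate_range: int = 200_000
    tail_bins: int = 10
    qc_s: float = 0.06
    xf: float = 1.5
    p_cutoff: float = 1e-10
    peak_min: float = 10.0
    exclusion: int = 10_000
    alpha_screen: float = 0.05
    alpha_posthoc: float = 0.05
    min_contacts: float = 1000.0
    r2_min: float = 0.7
    ld_window: int = 1_000_000
    n_background: int = 10_000
    # enrichment simulation
    n_leads: int = 200
    proxies_per_lead: int = 3
    planted_enrichment: float = 3.0
    n_controls: int = 50
    run_enrichment: bool = True
    # expression simulation
    expression_effect: float = 1.0
    expression_noise_sd: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "loop_distance" in data:
            data["loop_distance"] = tuple(data["loop_distance"])
        return cls(**data)

    def echo(self) -> str:
        # paths are not computation parameters; keep headers machine-stable
        params = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
            if k != "outdir"
        }
        return json.dumps(params, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pidscape\tseed={config.seed}\tparams={config.echo()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic dataset; returns the artifact dict and
    writes all tables under config.outdir."""
    os.makedirs(config.outdir, exist_ok=True)
    out = {}
    simcfg = synth.SimConfig(
        decay_exponent=config.decay_exponent,
        nb_dispersion=config.nb_dispersion,
        replicates_per_condition=config.replicates_per_condition,
        target_depth=config.target_depth,
        seed=config.seed,
        bin_size=config.bin_size,
    )
    layout, genes, cres, _ = synth.make_genome(
        simcfg, config.n_genes, config.n_cres, chrom_length=config.chrom_length
    )
    loops, anchor_cres = synth.plant_loops(
        layout,
        genes,
        config.n_loops,
        base_enhancement=config.base_enhancement,
        condition_factors={"a": config.condition_factor_a},
        distance_range=config.loop_distance,
        anchor_width=config.anchor_width,
        seed=config.seed,
    )
    all_cres = pd.concat(
        [cres[["chrom", "start", "end", "name"]], anchor_cres], ignore_index=True
    ).sort_values(["chrom", "start"], ignore_index=True)
    promoters = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": (genes["start"] - config.viewpoint_halfwidth).clip(lower=0),
            "end": genes["start"] + config.viewpoint_halfwidth,
        }
    )
    mask = synth.build_inactive_mask(
        layout, [genes[["chrom", "start", "end"]], promoters, all_cres]
    )
    truth = synth.TruthTables(loops=loops, inactive_mask=mask)
    write_bed(genes, os.path.join(config.outdir, "genes.bed"))
    write_bed(all_cres, os.path.join(config.outdir, "cres.bed"))
    write_bed(mask, os.path.join(config.outdir, "inactive_mask.bed"))
    logger.info("simulated genome: %d genes, %d CREs, %d loops",
                len(genes), len(all_cres), len(loops))

    matrices = {}
    for cond in ("a", "b"):
        matrices[cond] = synth.simulate_contacts(layout, loops, simcfg, condition=cond)
        for m in matrices[cond]:
            write_contacts(
                m, os.path.join(config.outdir, f"contacts_{m.label}.tsv")
            )
    out["matrices"] = matrices

    # depth scaling + merging, per the preprocessing contract
    all_reps = matrices["a"] + matrices["b"]
    scaled = scale_to_smallest(all_reps)
    scaled_by_cond = {
        "a": scaled[: len(matrices["a"])],
        "b": scaled[len(matrices["a"]):],
    }
    merged = {c: merge_replicates(ms) for c, ms in scaled_by_cond.items()}
    merged_all = merge_replicates(scaled)

    regions = bg.sample_background_regions(
        layout, mask, n=config.n_background, seed=config.seed
    )
    model = bg.fit_background(
        merged_all, regions, range_bp=config.range_bp, avg_bins=config.avg_bins,
        s=config.qc_s, fixate_range=config.fixate_range,
    )
    model = bg.flatten_far_field(model, config.fixate_range, config.tail_bins)
    model.to_tsv(os.path.join(config.outdir, "background.tsv"))
    out["background"] = model

    pid_tables = {}
    for cond in ("a", "b"):
        pid_table, summary, qc = pc.genomewide_pids(
            merged[cond], genes, model,
            range_bp=config.range_bp, avg_bins=config.avg_bins, qc_s=config.qc_s,
            fixate_range=config.fixate_range, xf=config.xf,
            p_cutoff=config.p_cutoff, peak_min=config.peak_min,
            exclusion=config.exclusion, halfwidth=config.viewpoint_halfwidth,
        )
        pid_tables[cond] = pid_table
        _write_tsv(pid_table, os.path.join(config.outdir, f"pids_{cond}.tsv"), config)
        _write_tsv(summary, os.path.join(config.outdir, f"gene_summary_{cond}.tsv"), config)
        logger.info("condition %s: %d PIDs, %d/%d viewpoints pass QC",
                    cond, len(pid_table), int(qc["qc_pass"].sum()), len(qc))
    out["pids"] = pid_tables

    targets = diff.candidate_targets(pid_tables["a"], pid_tables["b"])
    diff_table = diff.differential_pids(
        matrices["a"], matrices["b"], targets, genes,
        range_bp=config.range_bp, avg_bins=config.avg_bins,
        halfwidth=config.viewpoint_halfwidth,
        alpha_screen=config.alpha_screen, alpha_posthoc=config.alpha_posthoc,
        min_contacts=config.min_contacts,
    )
    _write_tsv(diff_table, os.path.join(config.outdir, "differential.tsv"), config)
    out["differential"] = diff_table

    classified = ann.classify_cres(all_cres, pid_tables["a"])
    _write_tsv(classified, os.path.join(config.outdir, "cre_classes.tsv"), config)
    out["cres"] = classified

    expr = synth.simulate_expression(
        truth, genes, config.expression_effect, config.expression_noise_sd,
        seed=config.seed,
    )
    _write_tsv(expr, os.path.join(config.outdir, "expression.tsv"), config)
    gex = ann.gex_linkage(diff_table, expr.set_index("gene")["log2fc"])
    _write_tsv(gex, os.path.join(config.outdir, "gex_linkage.tsv"), config)
    out["gex"] = gex

    if config.run_enrichment:
        pi_regions = classified[classified["cre_class"] == "PI"][
            ["chrom", "start", "end"]
        ].reset_index(drop=True)
        if len(pi_regions) == 0:
            pi_regions = anchor_cres[["chrom", "start", "end"]]
        vdata = synth.simulate_variants(
            layout, all_cres, config.planted_enrichment, config.n_leads,
            config.proxies_per_lead, seed=config.seed,
            tss_positions=genes[["chrom", "start"]],
            pi_regions=pi_regions,
        )
        sets = ve.expand_proxies(
            vdata["leads"], vdata["proxies"], vdata["features"],
            r2_min=config.r2_min, window=config.ld_window,
        )
        pool = ve.expand_proxies(
            vdata["pool"], vdata["proxies"], vdata["features"],
            r2_min=config.r2_min, window=config.ld_window,
        )
        res = ve.enrichment_test(
            sets, pi_regions, pool, n_controls=config.n_controls,
            seed=config.seed, trait="trait", region_set="PI-CRE",
        )
        enr = ve.bonferroni([res])
        _write_tsv(enr, os.path.join(config.outdir, "enrichment.tsv"), config)
        out["enrichment"] = enr
        truth.variant_labels = vdata["labels"]

    truth.write(os.path.join(config.outdir, "truth"))
    out["truth"] = truth
    out["genes"] = genes
    out["layout"] = layout
    report = evaluate(out, truth)
    with open(os.path.join(config.outdir, "evaluation.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    out["evaluation"] = report
    return out


def pid_recovery(pid_table: pd.DataFrame, loops) -> dict:
    """Overlap-based PID sensitivity/precision against planted loop anchors.

    A loop is recovered iff a called PID of its gene overlaps its CRE anchor;
    a PID is a true positive iff it overlaps a planted anchor of its gene.
    """
    recovered = 0
    for lp in loops:
        sub = pid_table[pid_table["gene"].astype(str) == lp.gene]
        hit = any(
            intervals_overlap(s, e, lp.anchor_b[0], lp.anchor_b[1])
            for s, e in zip(sub["start"], sub["end"])
        )
        recovered += int(hit)
    anchors_by_gene = {}
    for lp in loops:
        anchors_by_gene.setdefault(lp.gene, []).append(lp.anchor_b)
    tp = 0
    for _, row in pid_table.iterrows():
        anchors = anchors_by_gene.get(str(row["gene"]), [])
        if any(
            intervals_overlap(row["start"], row["end"], a0, a1)
            for a0, a1 in anchors
        ):
            tp += 1
    n_called = len(pid_table)
    return {
        "sensitivity": recovered / len(loops) if loops else np.nan,
        "precision": tp / n_called if n_called else np.nan,
        "n_loops": len(loops),
        "n_called": n_called,
    }


def differential_recovery(diff_table: pd.DataFrame, loops, condition: str = "a") -> dict:
    """Sensitivity/FDR of the differential verdict against planted
    condition-specific loops, with log2FC sign agreement."""
    changed = {lp.gene for lp in loops if lp.condition_factors.get(condition, 1.0) != 1.0}
    unchanged = {lp.gene for lp in loops} - changed
    called = diff_table[diff_table["called"]]
    called_genes = set(called["gene"].astype(str))
    tp_genes = changed & called_genes
    sign_ok = 0
    for g in tp_genes:
        lp = next(l for l in loops if l.gene == g)
        expect_up = lp.condition_factors.get(condition, 1.0) > 1.0
        sub = called[called["gene"].astype(str) == g]
        if all((sub["log2fc"] > 0) == expect_up):
            sign_ok += 1
    fp = len(unchanged & called_genes)
    return {
        "sensitivity": len(tp_genes) / len(changed) if changed else np.nan,
        "sign_correct": sign_ok,
        "n_changed": len(changed),
        "n_unchanged_called": fp,
        "fdr": fp / max(1, len(called_genes)),
    }


def evaluate(run_outputs: dict, truth: synth.TruthTables) -> dict:
    """EvaluationReport: PID recovery, differential recovery, enrichment
    fold error vs planted parameters."""
    report = {}
    if "pids" in run_outputs:
        report["pid"] = pid_recovery(run_outputs["pids"]["a"], truth.loops)
    if "differential" in run_outputs:
        report["differential"] = differential_recovery(
            run_outputs["differential"], truth.loops
        )
    if "enrichment" in run_outputs and run_outputs.get("enrichment") is not None:
        enr = run_outputs["enrichment"]
        report["enrichment"] = {
            "fold": float(enr["fold"].iloc[0]),
            "p_value": float(enr["p_value"].iloc[0]),
        }
    for key, block in report.items():
        for k, v in block.items():
            if isinstance(v, float) and not np.isnan(v) and k in (
                "sensitivity", "precision", "fdr"
            ):
                assert 0.0 <= v <= 1.0, f"{key}.{k} out of [0,1]"
    return report
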