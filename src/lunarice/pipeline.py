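"""End-to-end pipeline: simulate -> methylome -> expression -> networks ->
targets -> integrated report.

``run_all`` executes the whole single-sample analysis on a synthetic study
generated from ``RunConfig.seed``: context-wise methylome summaries and
group plus per-individual DMR calling, group and single-sample differential
expression for mRNA / miRNA / MRs, LIONESS single-sample networks with
degree-differential tests per layer, miRNA-to-MR target prediction with
expression- and interaction-evidence pairing, and a JSON/TSV report bundle
with a manifest capturing the configuration hash. Reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import integrate, io as lio, simulate, ssn, targets
from .config import RunConfig
from .diffexpr import (
    deg_group, deg_single_sample, demir_demr_single, load_mr_catalog,
)
from .methylome import (
    DmrParams, assign_dmrs_to_genes, call_dmrs, classify_dmg_contexts,
    compute_site_levels, context_genome_means,
)

logger = logging.getLogger(__name__)


def _stage_log(stage: str, t0: float, **counts) -> None:
    parts = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("[%s] %.1fs %s", stage, time.perf_counter() - t0, parts)


def run_all(config: RunConfig, outdir=None) -> dict:
    """Run every pipeline stage; optionally write the report bundle.

    Returns a results dictionary with the per-stage artifacts and the
    assembled report. Any stage failure propagates with the stage name.
    """
    results: dict = {}
    sim_cfg = config.sim

    t0 = time.perf_counter()
    try:
        sim = simulate.simulate_all(sim_cfg)
    except Exception as exc:  # pragma: no cover - defensive rewrap
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    results["sim"] = sim
    _stage_log("simulate", t0, genes=len(sim.gene_models),
               samples=len(sim.methylomes))

    # ---- methylome ----
    t0 = time.perf_counter()
    meta = sim.mrna.sample_meta
    levels = {}
    context_means = {}
    for sample, recs in sim.methylomes.items():
        lv, rep = compute_site_levels(recs, config.min_coverage)
        levels[sample] = lv
        context_means[sample] = context_genome_means(lv)
    results["context_means"] = context_means

    dmr_params = DmrParams(
        site_alpha=config.dmr_site_alpha, min_delta=config.dmr_min_delta,
        max_gap=config.dmr_max_gap, min_sites=config.dmr_min_sites,
        region_alpha=config.dmr_region_alpha,
    )
    dmrs: dict[str, pd.DataFrame] = {}
    dmgs: dict[str, pd.DataFrame] = {}
    for stage in sim_cfg.stages:
        ctrl_ids = [r["sample_id"] for r in sim_cfg.sample_sheet
                    if r["stage"] == stage and r["group"] == "control"]
        case_ids = [r["sample_id"] for r in sim_cfg.sample_sheet
                    if r["stage"] == stage and r["group"] == "flight"]
        ctrl = [sim.methylomes[s] for s in ctrl_ids]
        dmrs[f"{stage}:group"] = call_dmrs(
            ctrl, [sim.methylomes[s] for s in case_ids], dmr_params
        )
        for s in case_ids:
            dmrs[f"{stage}:{s}"] = call_dmrs(ctrl, [sim.methylomes[s]], dmr_params)
    for label, d in dmrs.items():
        dmg, summary = assign_dmrs_to_genes(d, sim.gene_models)
        dmgs[label] = dmg
    results["dmrs"] = dmrs
    results["dmgs"] = dmgs
    _stage_log("methylome", t0, comparisons=len(dmrs),
               total_dmrs=sum(len(d) for d in dmrs.values()))

    # ---- differential expression ----
    t0 = time.perf_counter()
    frames = []
    catalog = load_mr_catalog()
    for stage in sim_cfg.stages:
        frames.append(deg_group(
            sim.mrna, stage, layer="mRNA", alpha=config.de_alpha,
            lfc_gate=config.de_lfc_gate, eps=config.eps))
        frames.append(deg_group(
            sim.mirna, stage, layer="miRNA", alpha=config.de_alpha,
            lfc_gate=config.de_lfc_gate, eps=config.eps))
        case_ids = [r["sample_id"] for r in sim_cfg.sample_sheet
                    if r["stage"] == stage and r["group"] == "flight"]
        for s in case_ids:
            frames.append(deg_single_sample(
                sim.mrna, stage, s, layer="mRNA", alpha=config.de_alpha,
                lfc_gate=config.de_lfc_gate, eps=config.eps))
            demir, _ = demir_demr_single(
                sim.mirna, "miRNA", stage, s, alpha=config.de_alpha,
                eps=config.eps)
            frames.append(demir)
            demr, _ = demir_demr_single(
                sim.mrna, "MR", stage, s, mr_catalog=catalog,
                alpha=config.de_alpha, eps=config.eps)
            frames.append(demr)
    diff_expression = pd.concat(frames, ignore_index=True)
    results["diff_expression"] = diff_expression
    _stage_log("diffexpr", t0, n_calls=int(diff_expression["passed"].sum()))

    # ---- single-sample networks ----
    t0 = time.perf_counter()
    sample_order = [r["sample_id"] for r in sim_cfg.sample_sheet]
    dd_frames = []
    degree_vectors = {}
    for layer, matrix in (("mRNA", sim.mrna), ("miRNA", sim.mirna)):
        nets = ssn.lioness_networks(matrix, sample_order)
        dv = ssn.build_degree_vectors(nets, sample_order, tau=config.tau)
        degree_vectors[layer] = dv
        for stage in sim_cfg.stages:
            case_ids = [r["sample_id"] for r in sim_cfg.sample_sheet
                        if r["stage"] == stage and r["group"] == "flight"]
            for s in case_ids:
                dd = ssn.degree_diff_test(dv, meta, stage, s,
                                          alpha=config.de_alpha)
                dd["layer"] = layer
                dd_frames.append(dd)
    degree_diff = pd.concat(dd_frames, ignore_index=True)
    results["degree_diff"] = degree_diff
    results["degree_vectors"] = degree_vectors
    _stage_log("ssn", t0, n_dig=int(degree_diff["passed"].sum()))

    # ---- miRNA -> MR targets ----
    t0 = time.perf_counter()
    hits = targets.predict_targets(
        sim.mirna_seqs, sim.mr_transcripts,
        cutoff=config.target_cutoff, max_gaps=config.target_max_gaps,
    )
    results["target_hits"] = hits

    mr_ids = set(catalog["gene_id"])
    demir_res = diff_expression.loc[
        (diff_expression["layer"] == "miRNA")
        & (diff_expression["method"] == "single_sample")
    ]
    demr_res = diff_expression.loc[diff_expression["layer"] == "MR"]
    dimir_res = degree_diff.loc[degree_diff["layer"] == "miRNA"]
    dimr_res = degree_diff.loc[
        (degree_diff["layer"] == "mRNA")
        & degree_diff["molecule_id"].isin(mr_ids)
    ]
    pair_frames = [
        targets.pair_mirna_mr(hits, demir_res, demr_res, "expression"),
        targets.pair_mirna_mr(hits, dimir_res, dimr_res, "interaction"),
    ]
    non_empty = [f for f in pair_frames if not f.empty]
    pairs = (
        pd.concat(non_empty, ignore_index=True) if non_empty else pair_frames[0]
    )
    results["pairs"] = pairs
    _stage_log("targets", t0, n_hits=len(hits), n_pairs=len(pairs))

    # ---- integration ----
    t0 = time.perf_counter()
    overlaps = {}
    concordance = {}
    deg_mask = (diff_expression["layer"] == "mRNA") & diff_expression["passed"]
    for label, dmg in dmgs.items():
        stage, case = label.split(":")
        sub = diff_expression.loc[
            deg_mask
            & (diff_expression["stage"] == stage)
            & (diff_expression["case_sample"] == case)
        ]
        overlaps[label] = integrate.overlap_sets(dmg, diff_expression.loc[deg_mask],
                                                 stage, case)
        concordance[label] = integrate.direction_concordance(dmg, sub)
        overlaps[label]["context_multiplicity"] = classify_dmg_contexts(dmg)
    results["overlaps"] = overlaps
    results["concordance"] = concordance
    results["truth_recovery"] = _truth_recovery(sim, results)

    report = integrate.build_report(results, config=config.to_dict())
    results["report"] = report
    _stage_log("integrate", t0)

    if outdir is not None:
        _write_bundle(results, config, Path(outdir))
    return results


def _truth_recovery(sim, results) -> dict:
    """Sensitivity of each caller against the planted truth (appendix)."""
    truth = sim.truth
    out: dict = {}

    recovered = 0
    group_dmrs = [d for k, d in results["dmrs"].items() if k.endswith(":group")]
    for iv in truth.true_dmr_intervals:
        hit = any(
            (
                (d["context"] == iv["context"])
                & (d["start"] <= iv["end"])
                & (d["end"] >= iv["start"])
                & (d["direction"] == iv["direction"])
            ).any()
            for d in group_dmrs
        )
        recovered += bool(hit)
    n_dmr = len(truth.true_dmr_intervals)
    out["dmr_sensitivity_group"] = recovered / n_dmr if n_dmr else float("nan")

    de = results["diff_expression"]
    deg_called = set(
        de.loc[(de["layer"] == "mRNA") & (de["method"] == "group-welch")
               & de["passed"], "molecule_id"]
    )
    true_deg = set(truth.true_deg)
    out["deg_sensitivity_group"] = (
        len(deg_called & true_deg) / len(true_deg) if true_deg else float("nan")
    )

    dd = results["degree_diff"]
    dig_called = set(dd.loc[(dd["layer"] == "mRNA") & dd["passed"], "molecule_id"])
    true_dig = set(truth.true_dig_ids)
    out["dig_sensitivity_any_sample"] = (
        len(dig_called & true_dig) / len(true_dig) if true_dig else float("nan")
    )

    hits = results["target_hits"]
    found = 0
    for rec in truth.true_target_pairs:
        sub = hits.loc[
            (hits["mirna_id"] == rec["mirna_id"])
            & (hits["transcript_id"] == rec["transcript_id"])
            & (hits["site_start"] <= rec["site_end"])
            & (hits["site_end"] >= rec["site_start"])
        ]
        found += not sub.empty
    n_sites = len(truth.true_target_pairs)
    out["target_site_recovery"] = found / n_sites if n_sites else float("nan")
    return out


def _write_bundle(results: dict, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    simulate.write_run(results["sim"], outdir / "inputs")
    for label, d in results["dmrs"].items():
        lio.write_tsv(d, outdir / f"dmrs_{label.replace(':', '_')}.tsv")
    for label, d in results["dmgs"].items():
        lio.write_tsv(d, outdir / f"dmgs_{label.replace(':', '_')}.tsv")
    lio.write_tsv(results["diff_expression"], outdir / "diff_expression.tsv")
    lio.write_tsv(results["degree_diff"], outdir / "degree_diff.tsv")
    for layer, dv in results["degree_vectors"].items():
        dv.to_csv(outdir / f"degrees_{layer}.tsv", sep="\t",
                  index_label="molecule_id")
    lio.write_tsv(results["target_hits"], outdir / "target_hits.tsv")
    lio.write_tsv(results["pairs"], outdir / "mirna_mr_pairs.tsv")
    integrate.write_report(results["report"], outdir / "report.json")

    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest = {
        "package": "lunarice",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    lio.write_json(manifest, outdir / "manifest.json")
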