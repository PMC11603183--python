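"""Cross-layer integration: set overlaps, direction concordance, enrichment.

Combines the per-layer calls (DMGs from the methylome, DEGs/DEmiRs/DEMRs
from expression, DIGs/DImiRs from the single-sample networks) into the
summary structures a study of this design reports: DMG x DEG overlaps per
methylation context, hypo/hyper vs up/down concordance tables, a generic
hypergeometric term-enrichment, shared-id sets across the flight
individuals, and a machine-readable per-run report bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd
from scipy import stats


def overlap_sets(
    dmgs: pd.DataFrame,
    diff_results: pd.DataFrame,
    stage: str,
    case_sample: str = "group",
) -> dict:
    """Exact set algebra between DMGs and passed differential calls.

    Reports overall and per-context DMG/DEG intersections plus the
    fraction of overlapping DEGs hit by exactly one DMG context.
    """
    de = diff_results.loc[
        (diff_results["stage"] == stage)
        & (diff_results["case_sample"] == case_sample)
        & diff_results["passed"]
    ]
    deg_ids = set(de["molecule_id"])
    dmg_ids = set(dmgs["gene_id"]) if not dmgs.empty else set()
    inter = dmg_ids & deg_ids

    per_context = {}
    for ctx in ("CG", "CHG", "CHH"):
        if dmgs.empty:
            ids = set()
        else:
            ids = set(
                dmgs.loc[dmgs["contexts"].str.contains(ctx, regex=False), "gene_id"]
            )
        per_context[ctx] = {
            "n_dmgs": len(ids),
            "n_overlap_degs": len(ids & deg_ids),
        }
    if not dmgs.empty:
        single_ctx = set(dmgs.loc[dmgs["n_contexts"] == 1, "gene_id"])
    else:
        single_ctx = set()
    return {
        "stage": stage,
        "case_sample": case_sample,
        "n_dmgs": len(dmg_ids),
        "n_degs": len(deg_ids),
        "n_overlap": len(inter),
        "per_context": per_context,
        "single_context_overlap_fraction": (
            len(inter & single_ctx) / len(inter) if inter else float("nan")
        ),
    }


def direction_concordance(dmgs: pd.DataFrame, diff_results: pd.DataFrame) -> dict:
    """Four-cell concordance between methylation and expression direction.

    Counts hypomethylated DMGs among up/downregulated DEGs and the hyper
    counterparts; a gene's methylation direction is its dominant-|delta|
    direction (mixed-direction genes carry an ambiguous flag upstream but
    are routed by the dominant rule here).
    """
    de = diff_results.loc[diff_results["passed"]]
    cells = {"hypo_up": 0, "hyper_down": 0, "hypo_down": 0, "hyper_up": 0}
    if dmgs.empty:
        return cells
    meth_dir = dmgs.set_index("gene_id")["direction"]
    for _, row in de.iterrows():
        g = row["molecule_id"]
        if g not in meth_dir.index:
            continue
        cells[f"{meth_dir[g]}_{row['direction']}"] += 1
    return cells


def hypergeometric_enrichment(
    query_ids,
    annotation: dict[str, set],
    background_ids,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of query genes per term.

    Significance is conventionally summarized as -log10(P); a
    Benjamini-Hochberg column is included alongside the raw p-values.
    """
    query = set(query_ids)
    background = set(background_ids)
    outside = query - background
    if outside:
        raise ValueError(f"query ids outside background: {sorted(outside)[:5]}")
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for term, ids in annotation.items():
        term_ids = set(ids) & background
        k = len(term_ids & query)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(term_ids), n_q))
        rows.append(
            {
                "term_id": term,
                "term_size": len(term_ids),
                "hits": k,
                "query_size": n_q,
                "background_size": n_bg,
                "p_value": p,
                "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_size", "hits", "query_size",
            "background_size", "p_value", "neg_log10_p",
        ],
    ).sort_values(["p_value", "term_id"]).reset_index(drop=True)
    if not df.empty:
        m = len(df)
        ranked = df["p_value"].to_numpy()
        bh = ranked * m / (np.arange(m) + 1)
        df["p_bh"] = np.minimum.accumulate(bh[::-1])[::-1].clip(max=1.0)
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df


def shared_ids(sets_by_sample: dict[str, set]) -> set:
    """Ids common to all individuals (empty input yields the empty set)."""
    sets = list(sets_by_sample.values())
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def build_report(results: dict, config: dict | None = None) -> dict:
    """Assemble the per-run report from upstream artifacts.

    ``results`` carries the pipeline outputs keyed by stage (see
    :mod:`lunarice.pipeline`); missing pieces raise a dependency error
    naming the absent stage. The report holds DMR counts by direction
    and context, per-sample DEG/DIG/DEmiR/DImiR counts, shared-id sets
    across the flight individuals, the miRNA-MR pairing table, and (for
    synthetic runs) a recovered-truth appendix.
    """
    required = ["dmrs", "diff_expression", "degree_diff"]
    for key in required:
        if key not in results:
            raise KeyError(f"report requires upstream artifact {key!r}")

    report: dict = {"schema_version": 1}
    if config is not None:
        report["config"] = config

    dmr_counts = []
    for label, dmrs in results["dmrs"].items():
        if dmrs.empty:
            continue
        grp = dmrs.groupby(["context", "direction"]).size()
        for (ctx, direction), n in grp.items():
            dmr_counts.append(
                {"comparison": label, "context": ctx,
                 "direction": direction, "n": int(n)}
            )
    report["dmr_counts"] = dmr_counts

    de = results["diff_expression"]
    de_counts = (
        de.loc[de["passed"]]
        .groupby(["layer", "method", "stage", "case_sample", "direction"])
        .size()
        .reset_index(name="n")
    )
    report["diff_expression_counts"] = de_counts.to_dict(orient="records")

    dd = results["degree_diff"]
    dd_counts = (
        dd.loc[dd["passed"]]
        .groupby(["layer", "stage", "case_sample"])
        .size()
        .reset_index(name="n")
    )
    report["degree_diff_counts"] = dd_counts.to_dict(orient="records")

    shared = {}
    for layer in dd["layer"].unique():
        for stage in dd["stage"].unique():
            sub = dd.loc[(dd["layer"] == layer) & (dd["stage"] == stage) & dd["passed"]]
            per_sample = {
                s: set(g["molecule_id"]) for s, g in sub.groupby("case_sample")
            }
            shared[f"{layer}:{stage}"] = sorted(shared_ids(per_sample))
    report["shared_interaction_ids"] = shared

    if "pairs" in results:
        report["mirna_mr_pairs"] = results["pairs"].to_dict(orient="records")
    if "overlaps" in results:
        report["overlaps"] = results["overlaps"]
    if "concordance" in results:
        report["concordance"] = results["concordance"]
    if "truth_recovery" in results:
        report["truth_recovery"] = results["truth_recovery"]
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
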