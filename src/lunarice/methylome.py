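"""Methylome summaries and differentially methylated region (DMR) calling.

Works on per-cytosine count tables of the kind produced by bisulfite
aligners (one row per cytosine: chrom, 1-based position, strand, methylated
count ``mc``, unmethylated count ``uc``, sequence context CG/CHG/CHH).
Provides site-level methylation fractions with a coverage filter, per-context
genome means, strand-aware metagene profiles, a two-stage DMR caller
(per-site Fisher exact tests on pooled counts, then merging of concordant
candidate sites with a Stouffer-combined region p-value), and assignment of
DMRs to genes via promoter/gene-body overlap.

The caller runs identically in group mode (several samples per side, counts
pooled within each side) and in single-sample mode (one case sample against
the pooled control replicates), which is how individual plants are compared
against their ground-control group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fisher_exact_two_sided, stouffer_combine

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: canonical column order for cytosine record tables
CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "mc", "uc", "context"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with strand; coordinates 1-based inclusive.

    The promoter is the 2 kb immediately upstream of the transcription
    start site in transcription sense (upstream of ``start`` for + genes,
    of ``end`` for - genes), clipped at position 1.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    def promoter(self, length: int = 2000) -> tuple[int, int] | None:
        if self.strand == "+":
            lo, hi = self.start - length, self.start - 1
        else:
            lo, hi = self.end + 1, self.end + length
        lo = max(lo, 1)
        if lo > hi:
            return None
        return lo, hi


def classify_context(seq: str, pos: int, strand: str) -> str:
    """Sequence context (CG/CHG/CHH) of the cytosine at 1-based ``pos``.

    On the minus strand the context is read off the reverse complement,
    i.e. from the G on the plus strand leftwards. H is any of A, C, T.
    """
    i = pos - 1
    if strand == "+":
        if i >= len(seq) or seq[i].upper() != "C":
            raise ValueError(f"position {pos}(+) is not a C")
        nxt = seq[i + 1].upper() if i + 1 < len(seq) else "N"
        nxt2 = seq[i + 2].upper() if i + 2 < len(seq) else "N"
    elif strand == "-":
        if i >= len(seq) or seq[i].upper() != "G":
            raise ValueError(f"position {pos}(-) is not a C on the minus strand")
        nxt = seq[i - 1].upper().translate(_COMPLEMENT) if i - 1 >= 0 else "N"
        nxt2 = seq[i - 2].upper().translate(_COMPLEMENT) if i - 2 >= 0 else "N"
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def compute_site_levels(
    records: pd.DataFrame, min_coverage: int = 4
) -> tuple[pd.DataFrame, dict]:
    """Per-site methylation levels mc/(mc+uc) with a coverage filter.

    Sites with coverage (mc+uc) below ``min_coverage`` (default 4) are
    dropped. Returns the retained table with ``level`` and ``coverage``
    columns plus a report of retention counts.
    """
    if (records["mc"] < 0).any() or (records["uc"] < 0).any():
        raise ValueError("negative methylated/unmethylated counts")
    cov = records["mc"] + records["uc"]
    keep = cov >= min_coverage
    out = records.loc[keep].copy()
    out["coverage"] = cov[keep]
    out["level"] = out["mc"] / out["coverage"]
    report = {
        "n_input": int(len(records)),
        "n_retained": int(keep.sum()),
        "n_dropped_low_coverage": int((~keep).sum()),
        "min_coverage": int(min_coverage),
    }
    return out, report


def context_genome_means(levels: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-context mean site level for one sample.

    Contexts with no retained sites appear with count 0 and missing mean,
    never as a silent zero.
    """
    rows = []
    for ctx in CONTEXTS:
        sub = levels.loc[levels["context"] == ctx, "level"]
        rows.append(
            {
                "context": ctx,
                "mean_level": float(sub.mean()) if len(sub) else np.nan,
                "sd_level": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
                "n_sites": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def metagene_profile(
    levels: pd.DataFrame,
    gene_models: list[GeneModel],
    flank: int = 2000,
    n_bins: tuple[int, int, int] = (20, 20, 20),
) -> pd.DataFrame:
    """Binned mean methylation around genes (upstream flank, body, downstream).

    Each site is assigned to at most one bin of its nearest gene (distance
    to the gene body; sites farther than ``flank`` from every gene are
    unassigned). Minus-strand genes are flipped so bin 0 of the upstream
    region is always the 5' end. Bins with no sites are absent from the
    output rather than reported as zero.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    nb_up, nb_body, nb_down = n_bins
    if not gene_models or levels.empty:
        return pd.DataFrame(
            columns=["context", "region", "bin", "mean_level", "n_sites"]
        )

    starts = np.array([g.start for g in gene_models])
    ends = np.array([g.end for g in gene_models])
    strands = np.array([g.strand for g in gene_models])
    chroms = np.array([g.chrom for g in gene_models])

    recs = []
    for chrom in np.unique(chroms):
        gi = np.where(chroms == chrom)[0]
        sub = levels[levels["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        # distance from each site to each gene body on this chromosome
        d = np.maximum.reduce(
            [starts[gi][None, :] - pos[:, None], pos[:, None] - ends[gi][None, :],
             np.zeros((len(pos), len(gi)), dtype=int)]
        )
        nearest = np.argmin(d, axis=1)
        dist = d[np.arange(len(pos)), nearest]
        g_idx = gi[nearest]
        ok = dist <= flank
        for si in np.where(ok)[0]:
            g = g_idx[si]
            p = pos[si]
            s, e, strand = starts[g], ends[g], strands[g]
            if s <= p <= e:
                frac = (p - s) / max(e - s, 1)
                if strand == "-":
                    frac = 1.0 - frac
                b = min(int(frac * nb_body), nb_body - 1)
                region = "body"
            elif p < s:
                off = flank - (s - p)  # 0 at the far 5' edge for + genes
                b = min(int(off / flank * nb_up), nb_up - 1)
                region = "upstream" if strand == "+" else "downstream"
                if strand == "-":
                    b = nb_down - 1 - b
            else:
                off = p - e - 1
                b = min(int(off / flank * nb_down), nb_down - 1)
                region = "downstream" if strand == "+" else "upstream"
                if strand == "-":
                    b = nb_up - 1 - b
            recs.append((sub["context"].iat[si], region, b, sub["level"].iat[si]))

    if not recs:
        return pd.DataFrame(
            columns=["context", "region", "bin", "mean_level", "n_sites"]
        )
    df = pd.DataFrame(recs, columns=["context", "region", "bin", "level"])
    out = (
        df.groupby(["context", "region", "bin"])["level"]
        .agg(mean_level="mean", n_sites="size")
        .reset_index()
    )
    out["n_sites"] = out["n_sites"].astype(int)
    return out


@dataclass
class DmrParams:
    """Thresholds for the two-stage DMR caller (all exposed, none hidden)."""

    site_alpha: float = 0.01      # per-site Fisher p threshold
    min_delta: float = 0.1        # per-site |level difference| threshold
    max_gap: int = 200            # bp between candidate sites merged into one region
    min_sites: int = 3            # minimum candidate sites per region
    region_alpha: float = 0.05    # region-level (Stouffer) p threshold
    contexts: tuple = CONTEXTS


DMR_COLUMNS = [
    "chrom", "start", "end", "context", "n_sites",
    "mean_level_control", "mean_level_case", "delta", "p_value", "direction",
]


def call_dmrs(
    control: list[pd.DataFrame],
    case: list[pd.DataFrame],
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Call DMRs between pooled control and pooled case cytosine tables.

    Pipeline: pool counts within each side per site; per-site two-sided
    Fisher exact test on [mc_case, uc_case; mc_ctrl, uc_ctrl]; candidate
    sites need site p < ``site_alpha`` and |level difference| >=
    ``min_delta``; same-direction candidates within ``max_gap`` bp merge
    into regions of >= ``min_sites`` sites; the region p-value is the
    Stouffer combination of the contributing site z-scores and regions
    with p < ``region_alpha`` are reported. Direction is hyper if the
    case level is higher, hypo otherwise. Sites with zero coverage on
    either side are skipped.
    """
    params = params or DmrParams()
    if not control or not case:
        raise ValueError("need at least one sample per side")

    def pool(tables: list[pd.DataFrame]) -> pd.DataFrame:
        cat = pd.concat(tables, ignore_index=True)
        return (
            cat.groupby(["chrom", "pos", "strand", "context"], as_index=False)[
                ["mc", "uc"]
            ].sum()
        )

    ctrl = pool(control).rename(columns={"mc": "mc_c", "uc": "uc_c"})
    cas = pool(case).rename(columns={"mc": "mc_s", "uc": "uc_s"})
    merged = ctrl.merge(cas, on=["chrom", "pos", "strand", "context"], how="inner")
    cov_c = merged["mc_c"] + merged["uc_c"]
    cov_s = merged["mc_s"] + merged["uc_s"]
    merged = merged.loc[(cov_c > 0) & (cov_s > 0)].reset_index(drop=True)
    if merged.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)

    lvl_c = merged["mc_c"] / (merged["mc_c"] + merged["uc_c"])
    lvl_s = merged["mc_s"] / (merged["mc_s"] + merged["uc_s"])
    delta = (lvl_s - lvl_c).to_numpy()

    # Fisher only where the effect-size gate can pass: cheap and exact.
    cand_effect = np.abs(delta) >= params.min_delta
    p_site = np.ones(len(merged))
    if cand_effect.any():
        idx = np.where(cand_effect)[0]
        p_site[idx] = fisher_exact_two_sided(
            merged["mc_s"].to_numpy()[idx],
            merged["uc_s"].to_numpy()[idx],
            merged["mc_c"].to_numpy()[idx],
            merged["uc_c"].to_numpy()[idx],
        )
    candidate = cand_effect & (p_site < params.site_alpha)

    merged["delta"] = delta
    merged["lvl_c"] = lvl_c
    merged["lvl_s"] = lvl_s
    merged["p_site"] = p_site

    regions = []
    cand = merged.loc[candidate].sort_values(["chrom", "context", "pos"])
    for (chrom, ctx), grp in cand.groupby(["chrom", "context"], sort=True):
        if ctx not in params.contexts:
            continue
        pos = grp["pos"].to_numpy()
        sgn = np.sign(grp["delta"].to_numpy())
        # break runs where the gap exceeds max_gap or the direction flips
        brk = np.where(
            (np.diff(pos) > params.max_gap) | (np.diff(sgn) != 0)
        )[0]
        bounds = np.concatenate([[0], brk + 1, [len(pos)]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < params.min_sites:
                continue
            block = grp.iloc[b0:b1]
            p_region = stouffer_combine(
                block["p_site"].to_numpy(), np.sign(block["delta"].to_numpy())
            )
            if p_region >= params.region_alpha:
                continue
            d = float(block["lvl_s"].mean() - block["lvl_c"].mean())
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(block["pos"].min()),
                    "end": int(block["pos"].max()),
                    "context": ctx,
                    "n_sites": int(len(block)),
                    "mean_level_control": float(block["lvl_c"].mean()),
                    "mean_level_case": float(block["lvl_s"].mean()),
                    "delta": d,
                    "p_value": p_region,
                    "direction": "hyper" if d > 0 else "hypo",
                }
            )
    out = pd.DataFrame(regions, columns=DMR_COLUMNS)
    return out.sort_values(["chrom", "start", "context"]).reset_index(drop=True)


def assign_dmrs_to_genes(
    dmrs: pd.DataFrame,
    gene_models: list[GeneModel],
    promoter_length: int = 2000,
) -> tuple[pd.DataFrame, dict]:
    """Assign DMRs to genes via >=1 bp overlap with promoter or gene body.

    A DMR may hit several genes; a gene with at least one contributing DMR
    becomes a differentially methylated gene (DMG). The summary classifies
    each DMR as promoter / body / intergenic (promoter takes precedence
    when a DMR spans the TSS boundary region for classification counts,
    while the per-gene flags record both).
    """
    gene_rows: dict[str, dict] = {}
    dmr_region = {}
    for i, dmr in dmrs.iterrows():
        hit_promoter = hit_body = False
        for g in gene_models:
            if g.chrom != dmr["chrom"]:
                continue
            if dmr["start"] <= g.end and dmr["end"] >= g.start:
                body = True
            else:
                body = False
            prom = g.promoter(promoter_length)
            in_prom = prom is not None and dmr["start"] <= prom[1] and dmr["end"] >= prom[0]
            if not (body or in_prom):
                continue
            hit_promoter |= in_prom
            hit_body |= body
            row = gene_rows.setdefault(
                g.gene_id,
                {
                    "gene_id": g.gene_id,
                    "contexts": set(),
                    "promoter": False,
                    "body": False,
                    "dmr_ids": [],
                    "deltas": [],
                    "directions": [],
                },
            )
            row["contexts"].add(dmr["context"])
            row["promoter"] |= in_prom
            row["body"] |= body
            row["dmr_ids"].append(int(i))
            row["deltas"].append(float(dmr["delta"]))
            row["directions"].append(dmr["direction"])
        if hit_promoter:
            dmr_region[i] = "promoter"
        elif hit_body:
            dmr_region[i] = "body"
        else:
            dmr_region[i] = "intergenic"

    records = []
    for row in gene_rows.values():
        # dominant direction by largest |delta|; flag genes mixing both
        k = int(np.argmax(np.abs(row["deltas"])))
        records.append(
            {
                "gene_id": row["gene_id"],
                "contexts": ",".join(sorted(row["contexts"])),
                "n_contexts": len(row["contexts"]),
                "promoter": row["promoter"],
                "body": row["body"],
                "dmr_ids": ",".join(map(str, row["dmr_ids"])),
                "direction": row["directions"][k],
                "ambiguous_direction": len(set(row["directions"])) > 1,
            }
        )
    dmgs = pd.DataFrame(
        records,
        columns=[
            "gene_id", "contexts", "n_contexts", "promoter", "body",
            "dmr_ids", "direction", "ambiguous_direction",
        ],
    )
    if not dmgs.empty:
        dmgs = dmgs.sort_values("gene_id").reset_index(drop=True)
    assigned = [r for r in dmr_region.values() if r != "intergenic"]
    summary = {
        "n_dmrs": int(len(dmrs)),
        "n_assigned": len(assigned),
        "n_promoter": sum(r == "promoter" for r in dmr_region.values()),
        "n_body_only": sum(r == "body" for r in dmr_region.values()),
        "n_intergenic": sum(r == "intergenic" for r in dmr_region.values()),
        "promoter_fraction": (
            sum(r == "promoter" for r in assigned) / len(assigned)
            if assigned
            else float("nan")
        ),
    }
    return dmgs, summary


def classify_dmg_contexts(dmgs: pd.DataFrame) -> dict[int, int]:
    """Partition DMGs by how many methylation contexts contribute (1/2/3)."""
    counts = {1: 0, 2: 0, 3: 0}
    for n in dmgs.get("n_contexts", pd.Series(dtype=int)):
        counts[int(n)] += 1
    return counts
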