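"""Synthetic multi-omics data with planted, recoverable ground truth.

Generates every input the analysis consumes, mirroring the study design it
is meant to exercise: a random genome with non-overlapping gene models,
per-cytosine methylation reports for 3 ground-control and 3 flight plants
at two growth stages (12 samples), mRNA and miRNA expression matrices with
correlated co-expression modules, and miRNA/transcript FASTA with planted
complementary sites. Effects are planted with known locations and sizes —
hypo/hyper DMRs inside gene promoters or bodies, log2 fold changes on a
slice of molecules, module reassignment ("rewiring") of interaction-shifted
molecules in the flight samples only, and near-perfect miRNA sites in MR
transcripts — and recorded in a :class:`SyntheticTruth` object so every
downstream caller can be scored against what was actually planted.

All randomness flows from ``SimConfig.seed`` through named child streams
(genome / methylome / expression / targets), so a fixed seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .diffexpr import ExpressionMatrix, load_mr_catalog
from .methylome import CYTOSINE_COLUMNS, GeneModel
from .targets import DEFAULT_CUTOFF, DEFAULT_PARAMS, _normalize, _pair_cost, _scan_one
from . import io as lio

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_BASE_PROBS = np.array([0.275, 0.225, 0.225, 0.275])  # GC content 0.45
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TRUTH_SCHEMA_VERSION = 1


@dataclass
class SyntheticTruth:
    """Everything that was planted, for scoring the callers."""

    schema_version: int = TRUTH_SCHEMA_VERSION
    true_dmr_intervals: list[dict] = field(default_factory=list)
    true_deg: dict[str, float] = field(default_factory=dict)       # gene -> log2FC
    true_demir: dict[str, float] = field(default_factory=dict)     # miRNA -> log2FC
    true_dig_ids: list[str] = field(default_factory=list)
    true_dimir_ids: list[str] = field(default_factory=list)
    true_target_pairs: list[dict] = field(default_factory=list)
    planted_pair_ids: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimResult:
    """In-memory bundle of one simulated study."""

    config: SimConfig
    genome: dict[str, str]
    gene_models: list[GeneModel]
    methylomes: dict[str, pd.DataFrame]
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    mirna_seqs: dict[str, str]
    mr_transcripts: dict[str, str]
    truth: SyntheticTruth


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("genome", "methylome", "expression", "targets")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# -- genome ------------------------------------------------------------------

def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping, strand-assigned gene models.

    Genes are separated by at least ``min_gene_gap`` (default 4 kb) so
    2 kb promoter/flank windows never collide; infeasible requests fail
    with both quantities named.
    """
    rng = rng or _rng_streams(config.seed)["genome"]
    seq = "".join(rng.choice(_BASES, size=config.genome_length, p=_BASE_PROBS))
    genome = {"chr1": seq}
    n = config.n_genes
    if n == 0:
        return genome, []
    lo, hi = config.gene_length
    lengths = rng.integers(lo, hi + 1, size=n)
    gap = config.min_gene_gap
    required = int(lengths.sum() + gap * (n + 1))
    if config.genome_length < required:
        raise ValueError(
            f"cannot place {n} genes (total {required} bp incl. {gap} bp gaps) "
            f"in a {config.genome_length} bp genome"
        )
    slack = config.genome_length - required
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    strands = rng.choice(np.array(["+", "-"]), size=n)

    # a handful of genes carry the packaged MR (methylation regulator) ids
    catalog = load_mr_catalog()
    mr_ids = list(catalog["gene_id"])
    mr_pos = rng.choice(n, size=min(len(mr_ids), n), replace=False)
    ids = [f"OsSim{i + 1:04d}" for i in range(n)]
    for j, p in enumerate(sorted(mr_pos)):
        ids[p] = mr_ids[j]

    genes = []
    cursor = 0
    for i in range(n):
        cursor += gap + int(extra[i])
        start = cursor + 1  # 1-based
        end = start + int(lengths[i]) - 1
        cursor = end
        genes.append(
            GeneModel(
                gene_id=ids[i], chrom="chr1", strand=str(strands[i]),
                start=start, end=end,
            )
        )
    return genome, genes


# -- methylome ---------------------------------------------------------------

def _cytosine_catalog(seq: str) -> pd.DataFrame:
    """All cytosines of a sequence with strand and context, vectorised."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"

    def contexts(pos, nxt_is_g, nxt2_is_g):
        ctx = np.where(nxt_is_g, "CG", np.where(nxt2_is_g, "CHG", "CHH"))
        return ctx

    # + strand: context read to the right
    pos_p = np.where(is_c)[0]
    nxt = np.zeros(len(pos_p), dtype=bool)
    nxt2 = np.zeros(len(pos_p), dtype=bool)
    ok1 = pos_p + 1 < len(arr)
    nxt[ok1] = is_g[pos_p[ok1] + 1]
    ok2 = pos_p + 2 < len(arr)
    nxt2[ok2] = is_g[pos_p[ok2] + 2]
    ctx_p = contexts(pos_p, nxt, nxt2)

    # - strand: a C on the minus strand is a G on the plus; context to the left
    pos_m = np.where(is_g)[0]
    nxt = np.zeros(len(pos_m), dtype=bool)
    nxt2 = np.zeros(len(pos_m), dtype=bool)
    ok1 = pos_m - 1 >= 0
    nxt[ok1] = is_c[pos_m[ok1] - 1]
    ok2 = pos_m - 2 >= 0
    nxt2[ok2] = is_c[pos_m[ok2] - 2]
    ctx_m = contexts(pos_m, nxt, nxt2)

    return pd.DataFrame(
        {
            "pos": np.concatenate([pos_p + 1, pos_m + 1]),
            "strand": np.concatenate(
                [np.full(len(pos_p), "+"), np.full(len(pos_m), "-")]
            ),
            "context": np.concatenate([ctx_p, ctx_m]),
        }
    ).sort_values("pos", kind="stable").reset_index(drop=True)


def _place_dmr_intervals(
    catalog: pd.DataFrame,
    gene_models: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Pick genomic intervals for the planted DMRs inside gene neighborhoods."""
    placed: list[dict] = []
    occupied: list[tuple[int, int]] = []
    for item in config.dmr_plan:
        ctx_pos = catalog.loc[catalog["context"] == item.context, "pos"].to_numpy()
        found = False
        for _ in range(200):
            g = gene_models[int(rng.integers(len(gene_models)))]
            prom = g.promoter()
            lo = min(prom[0], g.start) if prom else g.start
            hi = max(prom[1], g.end) if prom else g.end
            cand = ctx_pos[(ctx_pos >= lo) & (ctx_pos <= hi)]
            if len(cand) < item.n_sites:
                continue
            k0 = int(rng.integers(len(cand) - item.n_sites + 1))
            sites = cand[k0 : k0 + item.n_sites]
            start, end = int(sites[0]), int(sites[-1])
            if end - start + 1 > item.region_length:
                continue
            if any(start <= e and end >= s for s, e in occupied):
                continue
            occupied.append((start, end))
            placed.append(
                {
                    "chrom": "chr1",
                    "start": start,
                    "end": end,
                    "context": item.context,
                    "direction": item.direction,
                    "delta": item.delta,
                    "n_sites": item.n_sites,
                    "depth": item.depth,
                    "gene_id": g.gene_id,
                    "sites": [int(p) for p in sites],
                }
            )
            found = True
            break
        if not found:
            raise RuntimeError(
                f"could not place a {item.context} DMR of {item.n_sites} sites "
                f"within {item.region_length} bp near any gene"
            )
    return placed


def simulate_methylome(
    genome: dict[str, str],
    gene_models: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Per-sample cytosine reports with planted DMRs.

    Control samples share site-wise baseline methylation probabilities
    (beta-distributed around the per-context means, binomial counts given
    a Poisson depth — beta-binomial marginally). Flight samples shift the
    probability by the planted delta inside planted intervals only,
    clamped to [0, 1] with a logged warning when clamping occurs.
    """
    rng = rng or _rng_streams(config.seed)["methylome"]
    seq = genome["chr1"]
    catalog = _cytosine_catalog(seq)
    planted = (
        _place_dmr_intervals(catalog, gene_models, config, rng)
        if gene_models and config.dmr_plan
        else []
    )

    n = len(catalog)
    keep = rng.random(n) < config.site_fraction
    planted_pos = {}
    for iv in planted:
        for p in iv["sites"]:
            planted_pos[(p, iv["context"])] = iv
    key = list(zip(catalog["pos"].to_numpy(), catalog["context"].to_numpy()))
    forced = np.array([k in planted_pos for k in key])
    keep |= forced
    sites = catalog.loc[keep].reset_index(drop=True)

    means = sites["context"].map(config.baseline_levels).to_numpy(dtype=float)
    k = config.beta_concentration
    baseline = rng.beta(means * k, (1.0 - means) * k)

    delta = np.zeros(len(sites))
    fixed_depth = np.zeros(len(sites), dtype=int)
    skey = list(zip(sites["pos"].to_numpy(), sites["context"].to_numpy()))
    for i, kk in enumerate(skey):
        iv = planted_pos.get(kk)
        if iv is not None:
            delta[i] = iv["delta"]
            fixed_depth[i] = iv["depth"]

    flight_p = baseline + delta
    n_clamped = int(((flight_p < 0) | (flight_p > 1)).sum())
    if n_clamped:
        logger.warning(
            "clamped %d planted site probabilities to [0, 1]", n_clamped
        )
    flight_p = np.clip(flight_p, 0.0, 1.0)

    methylomes: dict[str, pd.DataFrame] = {}
    for row in config.sample_sheet:
        depth = rng.poisson(config.mean_depth, size=len(sites))
        depth = np.where(fixed_depth > 0, fixed_depth, depth)
        p = flight_p if row["group"] == "flight" else baseline
        mc = rng.binomial(depth, p)
        covered = depth > 0
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": sites["pos"].to_numpy()[covered],
                "strand": sites["strand"].to_numpy()[covered],
                "mc": mc[covered],
                "uc": (depth - mc)[covered],
                "context": sites["context"].to_numpy()[covered],
            },
            columns=CYTOSINE_COLUMNS,
        )
        methylomes[row["sample_id"]] = df
    return methylomes, planted


# -- expression --------------------------------------------------------------

def _partition_modules(
    ids: list[str], size_range: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Assign molecules to correlated modules with heterogeneous sizes."""
    lo, hi = size_range
    if lo < 3:
        raise ValueError("module size < 3 rejected (correlation undefined)")
    order = rng.permutation(len(ids))
    module = np.empty(len(ids), dtype=int)
    m = 0
    i = 0
    while i < len(ids):
        size = int(rng.integers(lo, hi + 1))
        # keep at least two modules so rewiring has somewhere to go
        if m == 0 and len(ids) - size < lo and len(ids) >= 2 * lo:
            size = len(ids) // 2
        if len(ids) - i - size < lo:
            size = len(ids) - i  # absorb the remainder into the last module
        module[order[i : i + size]] = m
        m += 1
        i += size
    return module


def _simulate_layer(
    ids: list[str],
    config: SimConfig,
    rng: np.random.Generator,
    deg_plan,
    dig_fraction: float,
    n_allzero: int,
    forced_deg: dict[str, float] | None = None,
    scale_mu: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """One expression layer: module-structured lognormal abundances.

    Returns (values, planted log2FC per molecule, rewired molecule ids).
    Planted fold changes multiply flight values by 2^log2FC; rewired
    molecules draw their module factor from a different module in flight
    samples only, leaving the expected level unchanged.
    """
    n = len(ids)
    module = _partition_modules(ids, config.module_size_range, rng)
    n_modules = int(module.max()) + 1
    mu = rng.lognormal(mean=scale_mu, sigma=1.0, size=n)
    s_ln = np.sqrt(np.log1p(config.noise_cv**2))
    lam = np.sqrt(config.module_corr) * s_ln
    eps_sd = np.sqrt(1.0 - config.module_corr) * s_ln

    forced_deg = dict(forced_deg or {})
    free = [i for i, g in enumerate(ids) if g not in forced_deg]
    rng.shuffle(free)
    planted: dict[str, float] = dict(forced_deg)
    cursor = 0
    for item in deg_plan:
        k = int(round(item.fraction * n))
        for i in free[cursor : cursor + k]:
            planted[ids[i]] = item.signed_log2fc
        cursor += k

    non_deg = [i for i in range(n) if ids[i] not in planted]
    rng.shuffle(non_deg)
    n_dig = int(round(dig_fraction * n))
    dig_idx = np.array(non_deg[:n_dig], dtype=int)
    rewired_module = module.copy()
    for i in dig_idx:
        choices = [m for m in range(n_modules) if m != module[i]]
        rewired_module[i] = choices[int(rng.integers(len(choices)))]

    samples = config.sample_sheet
    values = np.empty((n, len(samples)))
    for j, row in enumerate(samples):
        z = rng.normal(size=n_modules)
        eps = rng.normal(size=n)
        mod = rewired_module if row["group"] == "flight" else module
        x = mu * np.exp(lam * z[mod] + eps_sd * eps)
        if row["group"] == "flight":
            for g, lfc in planted.items():
                x[ids.index(g)] *= 2.0**lfc
        values[:, j] = x

    df = pd.DataFrame(values, index=ids, columns=[r["sample_id"] for r in samples])
    for k0 in range(n_allzero):
        df.loc[f"{ids[0][:5]}Zero{k0 + 1:02d}"] = 0.0
    df = df.round(4)
    return df, planted, [ids[i] for i in dig_idx]


def simulate_expression(
    gene_models: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    forced_deg: dict[str, float] | None = None,
    forced_demir: dict[str, float] | None = None,
    mirna_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """mRNA (FPKM-like) and miRNA (TPM-like) matrices with planted effects."""
    rng = rng or _rng_streams(config.seed)["expression"]
    gene_ids = [g.gene_id for g in gene_models]
    mirna_ids = mirna_ids or [f"sim-miR-{i + 1:03d}" for i in range(config.n_mirnas)]

    mrna_vals, deg, dig = _simulate_layer(
        gene_ids, config, rng, config.deg_plan, config.dig_fraction,
        config.n_allzero_genes, forced_deg=forced_deg,
    )
    mirna_vals, demir, dimir = _simulate_layer(
        mirna_ids, config, rng, config.demir_plan, config.dimir_fraction,
        config.n_allzero_mirnas, forced_deg=forced_demir, scale_mu=4.0,
    )
    meta = pd.DataFrame(config.sample_sheet)
    truth = {
        "true_deg": deg,
        "true_demir": demir,
        "true_dig_ids": dig,
        "true_dimir_ids": dimir,
    }
    return (
        ExpressionMatrix(mrna_vals, meta),
        ExpressionMatrix(mirna_vals, meta),
        truth,
    )


# -- miRNA target planting ---------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_BASE_PROBS))


def _mismatch_base(mirna_base: str, rng: np.random.Generator) -> str:
    """A target base that scores a full mismatch (not a pair, not a wobble)."""
    options = [
        b for b in "ACGT" if _pair_cost(mirna_base, b, DEFAULT_PARAMS) == 1.0
    ]
    return options[int(rng.integers(len(options)))]


def plant_mirna_targets(
    transcripts: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[dict[str, str], dict[str, str], list[dict]]:
    """Plant near-perfect miRNA complementary sites into transcripts.

    Each planted site is the reverse complement of its miRNA with
    ``budget`` non-seed mismatches (expectation exactly ``budget``),
    inserted at a recorded offset. miRNAs are rejection-sampled so that
    no *unplanted* (miRNA, transcript) pair contains a window scoring at
    or below ``cutoff``. Returns (mirna seqs, modified transcripts,
    planted-site records).
    """
    rng = rng or _rng_streams(config.seed)["targets"]
    L = config.mirna_length
    for tid, seq in transcripts.items():
        if len(seq) < L:
            raise ValueError(f"transcript {tid} shorter than the miRNA length {L}")

    mirnas: dict[str, str] = {}
    tnames = list(transcripts)
    for i in range(config.n_mirnas):
        for _ in range(50):
            cand = _random_seq(rng, L)
            clean = all(
                not _scan_one(cand, _normalize(transcripts[t], t), DEFAULT_PARAMS, 1, cutoff)
                for t in tnames
            )
            if clean:
                break
        else:
            raise RuntimeError("could not sample a non-targeting miRNA in 50 tries")
        mirnas[f"sim-miR-{i + 1:03d}"] = cand

    out = dict(transcripts)
    planted: list[dict] = []
    plan = config.target_plan
    mirna_names = list(mirnas)
    n_sites = min(plan.n_sites, len(tnames), len(mirna_names))
    chosen_t = rng.choice(len(tnames), size=n_sites, replace=False)
    chosen_m = rng.choice(len(mirna_names), size=n_sites, replace=False)
    for ti, mi in zip(chosen_t, chosen_m):
        tid = tnames[int(ti)]
        mid = mirna_names[int(mi)]
        mseq = mirnas[mid]
        site = mseq.translate(_COMPLEMENT)[::-1]  # perfect complement, 5'->3'
        # mutate `budget` non-seed positions; site index for miRNA pos p is L-p
        non_seed = [p for p in range(1, L + 1) if not (2 <= p <= 13)]
        mut_pos = rng.choice(len(non_seed), size=min(plan.budget, len(non_seed)),
                             replace=False)
        site_list = list(site)
        for mp in mut_pos:
            p = non_seed[int(mp)]
            site_list[L - p] = _mismatch_base(mseq[p - 1], rng)
        site = "".join(site_list)
        seq = out[tid]
        offset = int(rng.integers(0, len(seq) - L + 1))
        out[tid] = seq[:offset] + site + seq[offset + L :]
        planted.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "site_start": offset + 1,
                "site_end": offset + L,
                "budget": int(plan.budget),
            }
        )
    return mirnas, out, planted


# -- orchestration -----------------------------------------------------------

def simulate_all(config: SimConfig) -> SimResult:
    """Run every generator layer under one seed and cross-link the truth.

    The planted miRNA-MR pairs couple the layers: the first
    ``n_planted_pairs`` planted target sites get an opposite-direction
    expression planting (miRNA up / MR down) so the downstream pairing
    stage has a recoverable signal.
    """
    streams = _rng_streams(config.seed)
    genome, genes = generate_genome(config, streams["genome"])
    methylomes, planted_dmrs = simulate_methylome(
        genome, genes, config, streams["methylome"]
    )

    catalog = load_mr_catalog()
    mr_models = [g for g in genes if g.gene_id in set(catalog["gene_id"])]
    transcripts = {}
    for g in mr_models:
        sub = genome[g.chrom][g.start - 1 : g.end]
        transcripts[g.gene_id] = (
            sub if g.strand == "+" else sub.translate(_COMPLEMENT)[::-1]
        )
    mirna_seqs, transcripts, planted_sites = plant_mirna_targets(
        transcripts, config, streams["targets"]
    )

    forced_deg: dict[str, float] = {}
    forced_demir: dict[str, float] = {}
    pair_ids = []
    for rec in planted_sites[: config.n_planted_pairs]:
        forced_deg[rec["transcript_id"]] = -1.5   # MR down in flight
        forced_demir[rec["mirna_id"]] = 1.5       # its miRNA up in flight
        pair_ids.append(
            {"mirna_id": rec["mirna_id"], "mr_gene_id": rec["transcript_id"]}
        )

    mrna, mirna, expr_truth = simulate_expression(
        genes, config, streams["expression"],
        forced_deg=forced_deg, forced_demir=forced_demir,
        mirna_ids=list(mirna_seqs),
    )

    truth = SyntheticTruth(
        true_dmr_intervals=[
            {k: v for k, v in iv.items() if k != "sites"} for iv in planted_dmrs
        ],
        true_deg=expr_truth["true_deg"],
        true_demir=expr_truth["true_demir"],
        true_dig_ids=expr_truth["true_dig_ids"],
        true_dimir_ids=expr_truth["true_dimir_ids"],
        true_target_pairs=planted_sites,
        planted_pair_ids=pair_ids,
    )
    result = SimResult(
        config=config, genome=genome, gene_models=genes, methylomes=methylomes,
        mrna=mrna, mirna=mirna, mirna_seqs=mirna_seqs,
        mr_transcripts=transcripts, truth=truth,
    )
    self_check(result)
    return result


def self_check(result: SimResult) -> None:
    """Verify every truth entry is realized in the emitted artifacts."""
    emitted = {
        (s, p, c)
        for s, df in result.methylomes.items()
        for p, c in zip(df["pos"], df["context"])
    }
    for iv in result.truth.true_dmr_intervals:
        for sample in result.methylomes:
            if not any(
                (sample, p, iv["context"]) in emitted
                for p in range(iv["start"], iv["end"] + 1)
            ):
                raise AssertionError(
                    f"planted DMR {iv['start']}-{iv['end']} missing from {sample}"
                )
    for g in result.truth.true_deg:
        if g not in result.mrna.values.index:
            raise AssertionError(f"planted DEG {g} missing from the mRNA matrix")
    for m in result.truth.true_demir:
        if m not in result.mirna.values.index:
            raise AssertionError(f"planted DEmiR {m} missing from the miRNA matrix")
    for rec in result.truth.true_target_pairs:
        t = result.mr_transcripts[rec["transcript_id"]]
        site = t[rec["site_start"] - 1 : rec["site_end"]]
        if len(site) != len(result.mirna_seqs[rec["mirna_id"]]):
            raise AssertionError("planted site length mismatch")


def write_run(result: SimResult, outdir) -> None:
    """Write every generated artifact as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lio.write_fasta(result.genome, out / "genome.fasta")
    lio.write_gff3(result.gene_models, out / "genes.gff3")
    lio.write_bed(result.gene_models, out / "genes.bed")
    meth_dir = out / "methylomes"
    meth_dir.mkdir(exist_ok=True)
    for sample, df in result.methylomes.items():
        lio.write_cytosine_report(df, meth_dir / f"{sample}.cx.tsv")
    lio.write_expression_tsv(result.mrna.values, out / "expression_mrna.tsv")
    lio.write_expression_tsv(result.mirna.values, out / "expression_mirna.tsv")
    result.mrna.sample_meta.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    lio.write_fasta(result.mirna_seqs, out / "mirnas.fasta")
    lio.write_fasta(result.mr_transcripts, out / "mr_transcripts.fasta")
    result.truth.to_json(out / "truth.json")
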