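"""Methylome summaries, metagene profiles and the DMR caller."""

import numpy as np
import pandas as pd
import pytest

from lunarice.methylome import (
    DmrParams,
    GeneModel,
    assign_dmrs_to_genes,
    call_dmrs,
    classify_context,
    classify_dmg_contexts,
    compute_site_levels,
    context_genome_means,
    metagene_profile,
)


def records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc", "uc", "context"])


# -- context classification --------------------------------------------------

@pytest.mark.parametrize(
    "seq,pos,strand,expected",
    [
        ("AACGAA", 3, "+", "CG"),
        ("AACAGA", 3, "+", "CHG"),
        ("AACTTA", 3, "+", "CHH"),
        ("AACGAA", 4, "-", "CG"),     # G opposite the + strand C of a CG
        ("TTCTGAA", 5, "-", "CHG"),   # minus-strand C, context read leftwards
        ("TTAAGAA", 5, "-", "CHH"),
    ],
)
def test_classify_context(seq, pos, strand, expected):
    assert classify_context(seq, pos, strand) == expected


def test_classify_context_requires_cytosine():
    with pytest.raises(ValueError):
        classify_context("AAATAA", 2, "+")


def test_context_counts_invariant_under_reverse_complement(rng):
    comp = str.maketrans("ACGT", "TGCA")
    seq = "".join(rng.choice(list("ACGT"), size=400))
    rc = seq.translate(comp)[::-1]

    def count(s):
        out = {"CG": 0, "CHG": 0, "CHH": 0}
        for i, base in enumerate(s, start=1):
            if base == "C":
                out[classify_context(s, i, "+")] += 1
            if base == "G":
                out[classify_context(s, i, "-")] += 1
        return out

    assert count(seq) == count(rc)


# -- site levels -------------------------------------------------------------

def test_site_level_formula_and_coverage_filter():
    recs = records(
        [("chr1", 10, "+", 3, 1, "CG"), ("chr1", 20, "+", 3, 0, "CHH")]
    )
    lv, rep = compute_site_levels(recs)
    assert len(lv) == 1
    assert lv["level"].iloc[0] == pytest.approx(0.75)
    assert lv["coverage"].iloc[0] == 4
    assert rep["n_dropped_low_coverage"] == 1


def test_site_levels_exact_retention_count(rng):
    # 100 sites, exactly 37 with coverage < 4
    cov = np.concatenate([rng.integers(4, 40, 63), rng.integers(0, 4, 37)])
    rng.shuffle(cov)
    mc = rng.binomial(cov, 0.5)
    recs = records(
        [("chr1", int(i + 1), "+", int(m), int(c - m), "CG")
         for i, (c, m) in enumerate(zip(cov, mc))]
    )
    lv, rep = compute_site_levels(recs)
    assert len(lv) == 63 and rep["n_retained"] == 63


def test_site_levels_idempotent_and_bounded(small_sim):
    recs = small_sim.methylomes["TC1"]
    lv, _ = compute_site_levels(recs)
    lv2, rep2 = compute_site_levels(lv[["chrom", "pos", "strand", "mc", "uc", "context"]])
    assert rep2["n_dropped_low_coverage"] == 0
    assert lv["level"].between(0, 1).all()
    pd.testing.assert_series_equal(lv["level"], lv2["level"])


def test_site_levels_reject_negative_counts():
    with pytest.raises(ValueError):
        compute_site_levels(records([("chr1", 1, "+", -1, 2, "CG")]))


# -- genome means ------------------------------------------------------------

def test_context_means_simple_and_empty():
    lv, _ = compute_site_levels(records(
        [("chr1", 1, "+", 4, 6, "CG"), ("chr1", 5, "+", 6, 4, "CG")]
    ))
    means = context_genome_means(lv)
    cg = means.set_index("context").loc["CG"]
    assert cg["mean_level"] == pytest.approx(0.5)
    chh = means.set_index("context").loc["CHH"]
    assert chh["n_sites"] == 0 and np.isnan(chh["mean_level"])


def test_context_means_recover_simulated_baseline(small_sim, small_config):
    lv, _ = compute_site_levels(small_sim.methylomes["TC1"])
    means = context_genome_means(lv).set_index("context")
    for ctx, base in small_config.baseline_levels.items():
        row = means.loc[ctx]
        se = row["sd_level"] / np.sqrt(row["n_sites"])
        assert abs(row["mean_level"] - base) < 5 * se + 0.01


# -- metagene profile --------------------------------------------------------

def level_table(entries):
    df = records([(c, p, s, mc, uc, ctx) for c, p, s, mc, uc, ctx in entries])
    lv, _ = compute_site_levels(df)
    return lv


def test_metagene_upstream_bin_index():
    gene = GeneModel("g1", "chr1", "+", 10_000, 12_000)
    lv = level_table([("chr1", 9_900, "+", 5, 5, "CG")])  # 100 bp upstream
    prof = metagene_profile(lv, [gene])
    row = prof.iloc[0]
    assert (row["region"], row["bin"]) == ("upstream", 19)


def test_metagene_uniform_levels_give_flat_profile():
    gene = GeneModel("g1", "chr1", "+", 5_000, 7_000)
    entries = [("chr1", p, "+", 5, 5, "CG") for p in range(3_200, 9_000, 37)]
    prof = metagene_profile(level_table(entries), [gene])
    assert np.allclose(prof["mean_level"], 0.5)


def test_metagene_minus_strand_mirrors_plus():
    # same site layout; the minus-strand gene reverses the 5'->3' reading
    plus = GeneModel("g1", "chr1", "+", 5_000, 7_000)
    minus = GeneModel("g1", "chr1", "-", 5_000, 7_000)
    lv = level_table([("chr1", 4_900, "+", 8, 2, "CG")])  # 100 bp left of start
    p_row = metagene_profile(lv, [plus]).iloc[0]
    m_row = metagene_profile(lv, [minus]).iloc[0]
    assert (p_row["region"], p_row["bin"]) == ("upstream", 19)
    assert (m_row["region"], m_row["bin"]) == ("downstream", 0)


def test_metagene_rejects_bad_flank():
    with pytest.raises(ValueError):
        metagene_profile(level_table([]), [], flank=0)


# -- DMR calling -------------------------------------------------------------

def test_single_site_fisher_example():
    # [10,0] vs [0,10]: exact two-sided p ~ 1.08e-5, a clear candidate site
    ctrl = records([("chr1", 100, "+", 0, 10, "CG")])
    case = records([("chr1", 100, "+", 10, 0, "CG")])
    from lunarice._stats import fisher_exact_two_sided

    p = fisher_exact_two_sided([10], [0], [0], [10])[0]
    assert p == pytest.approx(1.082508822446903e-05, rel=1e-9)
    # one site can never form a region (min_sites=3) but must count as candidate
    out = call_dmrs([ctrl], [case])
    assert out.empty


def test_identical_sides_yield_no_dmrs():
    tbl = records([("chr1", p, "+", 5, 5, "CG") for p in range(100, 400, 20)])
    assert call_dmrs([tbl], [tbl.copy()]).empty


def test_planted_region_recovered_as_single_hypo_dmr():
    pos = list(range(1_000, 1_200, 20))
    ctrl = records([("chr1", p, "+", 12, 8, "CG") for p in pos])   # level 0.6
    case = records([("chr1", p, "+", 4, 16, "CG") for p in pos])   # level 0.2
    out = call_dmrs([ctrl, ctrl.copy(), ctrl.copy()], [case])
    assert len(out) == 1
    dmr = out.iloc[0]
    assert dmr["direction"] == "hypo"
    assert dmr["n_sites"] == len(pos)
    assert dmr["start"] == pos[0] and dmr["end"] == pos[-1]
    assert dmr["delta"] == pytest.approx(-0.4, abs=0.01)


def test_dmr_regions_split_at_large_gaps():
    pos = list(range(1_000, 1_100, 20)) + list(range(2_000, 2_100, 20))
    ctrl = records([("chr1", p, "+", 15, 5, "CG") for p in pos])
    case = records([("chr1", p, "+", 2, 18, "CG") for p in pos])
    out = call_dmrs([ctrl], [case], DmrParams(max_gap=200))
    assert len(out) == 2
    assert (out["n_sites"] == 5).all()


def test_planted_synthetic_dmrs_recovered(small_sim, small_config):
    ctrl = [small_sim.methylomes[s] for s in ("TC1", "TC2", "TC3")]
    case = [small_sim.methylomes[s] for s in ("TS1", "TS2", "TS3")]
    out = call_dmrs(ctrl, case)
    strong = [
        iv for iv in small_sim.truth.true_dmr_intervals if abs(iv["delta"]) >= 0.25
    ]
    hit = sum(
        (
            (out["context"] == iv["context"])
            & (out["start"] <= iv["end"])
            & (out["end"] >= iv["start"])
            & (out["direction"] == iv["direction"])
        ).any()
        for iv in strong
    )
    assert hit / len(strong) >= 0.9


# -- DMR -> gene assignment --------------------------------------------------

def dmr_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "n_sites",
                 "mean_level_control", "mean_level_case", "delta",
                 "p_value", "direction"],
    )


def test_dmr_inside_body_flags_body_only():
    g = GeneModel("g1", "chr1", "+", 10_000, 12_000)
    dmrs = dmr_frame([("chr1", 10_500, 10_700, "CG", 5, 0.6, 0.2, -0.4, 1e-4, "hypo")])
    dmgs, summary = assign_dmrs_to_genes(dmrs, [g])
    row = dmgs.iloc[0]
    assert row["body"] and not row["promoter"]
    assert summary["n_body_only"] == 1


def test_dmr_spanning_tss_flags_both_regions():
    g = GeneModel("g1", "chr1", "+", 10_000, 12_000)
    dmrs = dmr_frame([("chr1", 9_900, 10_100, "CG", 5, 0.2, 0.6, 0.4, 1e-4, "hyper")])
    dmgs, _ = assign_dmrs_to_genes(dmrs, [g])
    row = dmgs.iloc[0]
    assert row["body"] and row["promoter"]


def test_promoter_fraction_summary():
    genes = [GeneModel(f"g{i}", "chr1", "+", 10_000 + i * 20_000,
                       12_000 + i * 20_000) for i in range(10)]
    rows = []
    for i in range(10):
        base = 10_000 + i * 20_000
        if i < 6:  # in the promoter (2 kb upstream)
            rows.append(("chr1", base - 1_500, base - 1_300, "CG", 5,
                         0.6, 0.2, -0.4, 1e-4, "hypo"))
        else:      # in the body
            rows.append(("chr1", base + 500, base + 700, "CG", 5,
                         0.6, 0.2, -0.4, 1e-4, "hypo"))
    dmgs, summary = assign_dmrs_to_genes(dmr_frame(rows), genes)
    assert summary["promoter_fraction"] == pytest.approx(0.6)


def test_minus_strand_promoter_is_downstream_of_end():
    g = GeneModel("g1", "chr1", "-", 10_000, 12_000)
    assert g.promoter() == (12_001, 14_000)
    dmrs = dmr_frame([("chr1", 13_000, 13_100, "CG", 5, 0.6, 0.2, -0.4, 1e-4, "hypo")])
    dmgs, _ = assign_dmrs_to_genes(dmrs, [g])
    assert dmgs.iloc[0]["promoter"] and not dmgs.iloc[0]["body"]


def test_context_multiplicity_partition():
    genes = [GeneModel("g1", "chr1", "+", 10_000, 12_000),
             GeneModel("g2", "chr1", "+", 30_000, 32_000)]
    dmrs = dmr_frame([
        ("chr1", 10_100, 10_200, "CG", 5, 0.6, 0.2, -0.4, 1e-4, "hypo"),
        ("chr1", 30_100, 30_200, "CG", 5, 0.6, 0.2, -0.4, 1e-4, "hypo"),
        ("chr1", 31_000, 31_100, "CHH", 5, 0.1, 0.5, 0.4, 1e-4, "hyper"),
    ])
    dmgs, _ = assign_dmrs_to_genes(dmrs, genes)
    counts = classify_dmg_contexts(dmgs)
    assert counts == {1: 1, 2: 1, 3: 0}
    assert sum(counts.values()) == len(dmgs)
    # mixed-direction gene carries the ambiguity flag with dominant direction
    g2 = dmgs.set_index("gene_id").loc["g2"]
    assert g2["ambiguous_direction"] and g2["direction"] in ("hypo", "hyper")
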