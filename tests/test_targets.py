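"""Duplex scoring and target-site scanning against enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lunarice.targets import (
    DEFAULT_PARAMS,
    ScoringParams,
    _scan_one,
    pair_mirna_mr,
    predict_targets,
    score_duplex,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def pair_penalty(mb, tb, params=DEFAULT_PARAMS):
    """Independent per-pair penalty used by the enumeration oracle."""
    if (mb, tb) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return 0.0
    if (mb, tb) in (("G", "T"), ("T", "G")):
        return params.gu_wobble
    return params.mismatch


def sf(pos, params=DEFAULT_PARAMS):
    return params.seed_multiplier if params.seed_start <= pos <= params.seed_end else 1.0


def enumerate_best_score(mirna, window, params=DEFAULT_PARAMS):
    """Exhaustive enumeration of every <=1-gap alignment (oracle).

    Written as direct summation over explicit pairings, independent of
    the dynamic program it checks.
    """
    m = mirna.upper().replace("U", "T")
    r = window.upper().replace("U", "T")[::-1]
    L, Lw = len(m), len(r)
    scores = []
    if Lw == L:  # gapless
        scores.append(sum(pair_penalty(m[i], r[i]) * sf(i + 1) for i in range(L)))
    if Lw == L - 1:  # one miRNA base bulged out at index b
        for b in range(L):
            s = DEFAULT_PARAMS.gap * sf(b + 1)
            s += sum(pair_penalty(m[i], r[i]) * sf(i + 1) for i in range(b))
            s += sum(pair_penalty(m[i], r[i - 1]) * sf(i + 1) for i in range(b + 1, L))
            scores.append(s)
    if Lw == L + 1:  # one target base bulged out at reversed index g
        for g in range(L + 1):
            s = DEFAULT_PARAMS.gap * sf(min(g + 1, L))
            s += sum(pair_penalty(m[i], r[i]) * sf(i + 1) for i in range(g))
            s += sum(pair_penalty(m[i], r[i + 1]) * sf(i + 1) for i in range(g, L))
            scores.append(s)
    return min(scores)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# -- scoring rules -----------------------------------------------------------

def test_perfect_complement_scores_zero(rng):
    m = random_seq(rng, 21)
    score, aln, seed_mm = score_duplex(m, revcomp(m))
    assert score == 0.0 and seed_mm == 0
    assert set(aln[1]) == {"|"}


def test_gu_wobble_in_seed_scores_one(rng):
    m = "A" * 21  # miRNA all A; perfect site all T
    site = list(revcomp(m))
    # miRNA position 5 pairs site index L-5; G opposite A is a mismatch,
    # so use a miRNA U:G wobble instead: set miRNA pos 5 to T, site base to G
    m = m[:4] + "T" + m[5:]
    site = list(revcomp(m))
    site[21 - 5] = "G"  # T:G wobble at miRNA position 5 (seed, doubled)
    score, _, seed_mm = score_duplex(m, "".join(site))
    assert score == pytest.approx(1.0)  # 0.5 * 2
    assert seed_mm == 1


def test_seed_doubling_of_mismatch_penalty(rng):
    m = random_seq(rng, 21)
    for pos, expected in ((20, 1.0), (8, 2.0)):
        site = list(revcomp(m))
        idx = 21 - pos
        bad = next(b for b in "ACGT" if pair_penalty(m[pos - 1], b) == 1.0)
        site[idx] = bad
        score, _, _ = score_duplex(m, "".join(site))
        assert score == pytest.approx(expected)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    m=st.text(alphabet="ACGT", min_size=18, max_size=22),
    w=st.text(alphabet="ACGT", min_size=18, max_size=22),
)
def test_score_invariant_to_u_t_representation(m, w):
    if abs(len(m) - len(w)) > 1:
        w = w[: len(m)] if len(w) > len(m) else w + "A" * (len(m) - len(w))
    s1, _, _ = score_duplex(m, w)
    s2, _, _ = score_duplex(m.replace("T", "U"), w.replace("T", "U"))
    assert s1 == s2


def test_rejects_invalid_characters():
    with pytest.raises(ValueError):
        score_duplex("ACGTN" * 4, "ACGT" * 5)


def test_adding_a_mismatch_never_decreases_expectation(rng):
    for _ in range(30):
        m = random_seq(rng, 20)
        site = list(revcomp(m))
        s0, _, _ = score_duplex(m, "".join(site))
        i = int(rng.integers(20))
        orig = site[i]
        site[i] = next(b for b in "ACGT" if b != orig)
        s1, _, _ = score_duplex(m, "".join(site))
        assert s1 >= s0


# -- DP vs exhaustive enumeration -------------------------------------------

@pytest.mark.parametrize("lw_delta", [-1, 0, 1])
def test_dp_equals_enumeration_on_random_windows(rng, lw_delta):
    for _ in range(60):
        L = int(rng.integers(18, 25))
        m = random_seq(rng, L)
        w = random_seq(rng, L + lw_delta)
        got, _, _ = score_duplex(m, w)
        assert got == pytest.approx(enumerate_best_score(m, w), abs=1e-9)


def test_window_scan_equals_per_window_dp(rng):
    m = random_seq(rng, 21)
    t = random_seq(rng, 300)
    scan = {(o, lw): s for o, lw, s in _scan_one(m, t, DEFAULT_PARAMS, 1)}
    for (o, lw), s in scan.items():
        ref, _, _ = score_duplex(m, t[o : o + lw])
        assert s == pytest.approx(ref, abs=1e-9)
    # completeness: every placement of every admissible length is scored
    for lw in (20, 21, 22):
        for o in range(0, 300 - lw + 1):
            assert (o, lw) in scan


# -- prediction --------------------------------------------------------------

def test_planted_perfect_site_found_at_offset(rng):
    m = random_seq(rng, 21)
    t = random_seq(rng, 200) + revcomp(m) + random_seq(rng, 200)
    hits = predict_targets({"mir1": m}, {"tx1": t}, cutoff=0.0)
    assert len(hits) == 1
    hit = hits.iloc[0]
    assert hit["site_start"] == 201 and hit["site_end"] == 221
    assert hit["expectation"] == 0.0


def test_cutoff_zero_reports_only_perfect_sites(rng):
    m = random_seq(rng, 21)
    near = list(revcomp(m))
    near[0] = next(b for b in "ACGT" if b != near[0])
    t = random_seq(rng, 60) + "".join(near) + random_seq(rng, 60)
    hits = predict_targets({"mir1": m}, {"tx1": t}, cutoff=0.0)
    assert hits.empty


def test_empty_inputs_give_empty_result():
    assert predict_targets({}, {"tx": "ACGT" * 30}).empty


def test_no_hit_reported_above_cutoff(rng):
    m = random_seq(rng, 21)
    t = random_seq(rng, 2000)
    hits = predict_targets({"mir1": m}, {"tx1": t}, cutoff=5.0)
    assert (hits["expectation"] <= 5.0).all()


def test_translation_inhibition_annotation(rng):
    m = random_seq(rng, 21)
    central = list(revcomp(m))
    idx = 21 - 10  # site index pairing miRNA position 10
    central[idx] = next(b for b in "ACGT"
                        if pair_penalty(m[9], b) == 1.0)
    t = random_seq(rng, 40) + "".join(central) + random_seq(rng, 40)
    hits = predict_targets({"mir1": m}, {"tx1": t}, cutoff=5.0)
    on_site = hits[(hits["site_start"] <= 61) & (hits["site_end"] >= 41)]
    assert bool(on_site.iloc[0]["translation_inhibition"])
    # a perfect site carries no central-mismatch flag
    t2 = random_seq(rng, 40) + revcomp(m) + random_seq(rng, 40)
    hits2 = predict_targets({"mir1": m}, {"tx1": t2}, cutoff=0.0)
    assert not bool(hits2.iloc[0]["translation_inhibition"])


def test_overlapping_hits_collapse_to_best_site(rng):
    m = random_seq(rng, 21)
    t = random_seq(rng, 50) + revcomp(m) + random_seq(rng, 50)
    hits = predict_targets({"mir1": m}, {"tx1": t}, cutoff=5.0)
    within = hits[(hits["site_start"] <= 71) & (hits["site_end"] >= 51)]
    assert len(within) == 1
    assert within.iloc[0]["expectation"] == 0.0


# -- pairing -----------------------------------------------------------------

def diff_frame(rows):
    cols = ["molecule_id", "direction", "stage", "case_sample", "passed"]
    return pd.DataFrame(rows, columns=cols)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "expectation",
                                       "site_start", "site_end"])


def test_opposite_direction_pair_flagged():
    hits = hits_frame([("mir1", "g1", 1.0, 10, 30)])
    mi = diff_frame([("mir1", "up", "tillering", "TS1", True)])
    mr = diff_frame([("g1", "down", "tillering", "TS1", True)])
    pairs = pair_mirna_mr(hits, mi, mr, "expression")
    assert len(pairs) == 1 and pairs.iloc[0]["opposite"]
    assert pairs.iloc[0]["method"] == "Fold change"


def test_same_direction_pair_retained_not_opposite():
    hits = hits_frame([("mir1", "g1", 1.0, 10, 30)])
    mi = diff_frame([("mir1", "up", "heading", "HS1", True)])
    mr = diff_frame([("g1", "up", "heading", "HS1", True)])
    pairs = pair_mirna_mr(hits, mi, mr, "interaction")
    assert len(pairs) == 1 and not pairs.iloc[0]["opposite"]
    assert pairs.iloc[0]["method"] == "SSN"


def test_no_hit_means_no_pair():
    mi = diff_frame([("mir1", "up", "tillering", "TS1", True)])
    mr = diff_frame([("g1", "down", "tillering", "TS1", True)])
    assert pair_mirna_mr(hits_frame([]), mi, mr, "expression").empty


def test_stage_and_sample_must_match():
    hits = hits_frame([("mir1", "g1", 1.0, 10, 30)])
    mi = diff_frame([("mir1", "up", "tillering", "TS1", True)])
    mr = diff_frame([("g1", "down", "tillering", "TS2", True)])
    assert pair_mirna_mr(hits, mi, mr, "expression").empty
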