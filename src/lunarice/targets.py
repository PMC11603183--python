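"""Plant miRNA target prediction with an expectation (penalty) score.

Scores a miRNA against a same-length window of a transcript by summing
penalties over the antiparallel duplex: 1.0 per mismatch, 0.5 per G:U
wobble, 2.0 per gap/bulge, with penalties at miRNA positions 2-13 (the 5'
seed region, 1-based from the miRNA 5' end) doubled. Lower is better; a
perfect reverse complement scores 0. ``score_duplex`` finds the optimal
alignment of one window by dynamic programming over match/mismatch/gap
states; ``predict_targets`` scans every window of every transcript with a
vectorised prefix-sum scheme that reproduces the DP exactly for the
default <=1-gap search space, and reports hits with expectation <= cutoff
(default 5.0), collapsing overlapping hits of the same miRNA/transcript
pair to the best site.

T and U are interchangeable on input; alignments are reported with the
miRNA written 3'->5' over the target site written 5'->3'.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class ScoringParams:
    """Penalty constants for duplex scoring (psRNATarget-style defaults)."""

    mismatch: float = 1.0
    gu_wobble: float = 0.5
    gap: float = 2.0
    seed_start: int = 2      # 1-based miRNA position, inclusive
    seed_end: int = 13
    seed_multiplier: float = 2.0

    def seed_factor(self, pos: int) -> float:
        return self.seed_multiplier if self.seed_start <= pos <= self.seed_end else 1.0


DEFAULT_PARAMS = ScoringParams()
DEFAULT_CUTOFF = 5.0

HIT_COLUMNS = [
    "mirna_id", "transcript_id", "expectation", "site_start", "site_end",
    "seed_mismatches", "translation_inhibition",
    "aln_mirna", "aln_pairing", "aln_target",
]


def _central_mismatch(aln: tuple[str, str, str]) -> bool:
    """Unpaired/mispaired miRNA position 10 or 11 (cleavage-blocking).

    Annotation only; hits are never filtered on it.
    """
    a_m, a_p, _ = aln
    pos = 0
    # alignment strings run miRNA 3'->5'; walk right-to-left over 5'->3'
    for mb, pb in zip(reversed(a_m), reversed(a_p)):
        if mb != "-":
            pos += 1
            if pos in (10, 11) and pb != "|":
                return True
    return False


def _normalize(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(_BASES)
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)}")
    return s


def _pair_cost(mirna_base: str, target_base: str, params: ScoringParams) -> float:
    """Penalty of pairing one miRNA base with one target base (both 5'->3' sense)."""
    pair = (mirna_base, target_base)
    if pair in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return 0.0
    if pair in (("G", "T"), ("T", "G")):  # G:U wobble in RNA terms
        return params.gu_wobble
    return params.mismatch


def score_duplex(
    mirna: str,
    window: str,
    params: ScoringParams | None = None,
    max_gaps: int = 1,
) -> tuple[float, tuple[str, str, str], int]:
    """Optimal expectation for one miRNA against one target window.

    Dynamic programming over (miRNA position, window position, gaps used)
    with pair / miRNA-bulge / target-bulge moves; gap penalties take the
    seed factor of the next miRNA position to pair. Returns
    ``(expectation, (mirna 3'->5', pairing, target 5'->3'), seed_mismatches)``
    where the pairing line marks '|' Watson-Crick, 'o' wobble, '.'
    mismatch and '-' gap, and ``seed_mismatches`` counts non-Watson-Crick
    events (including gaps) at miRNA positions 2-13.
    """
    params = params or DEFAULT_PARAMS
    m = _normalize(mirna, "mirna")
    w = _normalize(window, "window")
    L, Lw = len(m), len(w)
    if not (L - max_gaps <= Lw <= L + max_gaps):
        raise ValueError(
            f"window length {Lw} incompatible with miRNA length {L} "
            f"and gap budget {max_gaps}"
        )
    r = w[::-1]  # r[j] pairs m[j] in a gapless alignment
    inf = float("inf")
    # dp[(i, j, g)] = best cost consuming m[:i] and r[:j] with g gaps
    dp = {(0, 0, 0): 0.0}
    back: dict[tuple[int, int, int], tuple[tuple[int, int, int], str]] = {}
    for i in range(L + 1):
        for j in range(Lw + 1):
            for g in range(max_gaps + 1):
                key = (i, j, g)
                if key not in dp:
                    continue
                base = dp[key]
                if i < L and j < Lw:
                    c = base + _pair_cost(m[i], r[j], params) * params.seed_factor(i + 1)
                    nk = (i + 1, j + 1, g)
                    if c < dp.get(nk, inf):
                        dp[nk] = c
                        back[nk] = (key, "pair")
                if g < max_gaps and i < L:  # miRNA base bulged out
                    c = base + params.gap * params.seed_factor(i + 1)
                    nk = (i + 1, j, g + 1)
                    if c < dp.get(nk, inf):
                        dp[nk] = c
                        back[nk] = (key, "mgap")
                if g < max_gaps and j < Lw:  # target base bulged out
                    c = base + params.gap * params.seed_factor(min(i + 1, L))
                    nk = (i, j + 1, g + 1)
                    if c < dp.get(nk, inf):
                        dp[nk] = c
                        back[nk] = (key, "tgap")
    finals = {g: dp[(L, Lw, g)] for g in range(max_gaps + 1) if (L, Lw, g) in dp}
    g_best = min(finals, key=finals.get)
    best = finals[g_best]

    # traceback -> alignment strings and seed mismatch count
    moves = []
    key = (L, Lw, g_best)
    while key != (0, 0, 0):
        key, mv = back[key]
        moves.append(mv)
    moves.reverse()
    a_m, a_p, a_t = [], [], []
    i = j = 0
    seed_mm = 0
    for mv in moves:
        if mv == "pair":
            cost = _pair_cost(m[i], r[j], params)
            a_m.append(m[i])
            a_t.append(r[j])
            a_p.append("|" if cost == 0 else ("o" if cost == params.gu_wobble else "."))
            if cost > 0 and params.seed_start <= i + 1 <= params.seed_end:
                seed_mm += 1
            i += 1
            j += 1
        elif mv == "mgap":
            a_m.append(m[i])
            a_t.append("-")
            a_p.append("-")
            if params.seed_start <= i + 1 <= params.seed_end:
                seed_mm += 1
            i += 1
        else:
            a_m.append("-")
            a_t.append(r[j])
            a_p.append("-")
            if params.seed_start <= min(i + 1, L) <= params.seed_end:
                seed_mm += 1
            j += 1
    # miRNA 3'->5' over target 5'->3': reverse all three lines
    aln = ("".join(reversed(a_m)), "".join(reversed(a_p)), "".join(reversed(a_t)))
    return best, aln, seed_mm


def _cost_matrix(mirna: str, params: ScoringParams) -> np.ndarray:
    """M[k, b]: penalty of transcript base b at forward-window offset k.

    Forward-window position k pairs miRNA index L-1-k (the duplex is
    antiparallel), already including the seed factor of that position.
    """
    L = len(mirna)
    M = np.empty((L, 4))
    for k in range(L):
        i = L - 1 - k
        f = params.seed_factor(i + 1)
        for b, base in enumerate(_BASES):
            M[k, b] = _pair_cost(mirna[i], base, params) * f
    return M


def _scan_one(
    mirna: str,
    transcript: str,
    params: ScoringParams,
    max_gaps: int,
    cutoff: float = float("inf"),
) -> list[tuple[int, int, float]]:
    """Window placements whose optimal <=max_gaps-gap score is <= cutoff.

    Returns (start0, window_length, expectation); uses prefix sums of the
    gapless cost matrix so each one-gap score is an O(1) combination,
    matching :func:`score_duplex` exactly.
    """
    L = len(mirna)
    N = len(transcript)
    if N < L - max_gaps:
        return []
    T = np.fromiter((_BASE_INDEX[c] for c in transcript), dtype=np.int64, count=N)
    M = _cost_matrix(mirna, params)
    sf = np.array([params.seed_factor(p) for p in range(1, L + 1)])

    n_off = N - L + 1
    out: list[tuple[int, int, float]] = []
    if n_off > 0:
        idx = np.arange(n_off)[:, None] + np.arange(L)[None, :]
        C = M[np.arange(L)[None, :], T[idx]]
        P = np.zeros((n_off, L + 1))
        P[:, 1:] = np.cumsum(C, axis=1)
        s0 = P[:, L]
        for o in np.where(s0 <= cutoff)[0]:
            out.append((int(o), L, float(s0[o])))
        if max_gaps >= 1:
            # target bulge: window length L+1 starting at o, unpaired base at
            # reversed-window index g; score = gap*sf(min(g+1,L))
            #   + prefix(o, L-g) + suffix(o+1, L-g)
            if n_off > 1:
                g = np.arange(L + 1)
                gap_pen = params.gap * sf[np.minimum(g, L - 1)]
                t = L - g  # prefix length
                o_arr = np.arange(n_off - 1)
                scores = (
                    gap_pen[None, :]
                    + P[o_arr[:, None], t[None, :]]
                    + (P[o_arr[:, None] + 1, L] - P[o_arr[:, None] + 1, t[None, :]])
                )
                best_tb = scores.min(axis=1)
                for o in np.where(best_tb <= cutoff)[0]:
                    out.append((int(o), L + 1, float(best_tb[o])))
            # miRNA bulge: window length L-1 starting at o (o>=1 via prefix
            # trick; boundary starts handled by the DP directly); unpaired
            # miRNA index b
            if N >= L - 1:
                b = np.arange(L)
                gap_pen = params.gap * sf[b]
                t1 = L - 1 - b  # prefix length at offset o
                t2 = L - b      # suffix start at offset o-1
                if n_off >= 2:
                    o_arr = np.arange(1, n_off)
                    scores = (
                        gap_pen[None, :]
                        + P[o_arr[:, None], t1[None, :]]
                        + (P[o_arr[:, None] - 1, L] - P[o_arr[:, None] - 1, t2[None, :]])
                    )
                    best_mb = scores.min(axis=1)
                    for k in np.where(best_mb <= cutoff)[0]:
                        out.append((int(o_arr[k]), L - 1, float(best_mb[k])))
                # starts not coverable by the prefix trick
                for o in {0, n_off} & set(range(0, N - (L - 1) + 1)):
                    s, _, _ = score_duplex(
                        mirna, transcript[o : o + L - 1], params, max_gaps
                    )
                    if s <= cutoff:
                        out.append((o, L - 1, s))
    else:
        # transcript shorter than the miRNA: only shrunken windows fit
        for o in range(N - (L - max_gaps) + 1):
            s, _, _ = score_duplex(
                mirna, transcript[o : o + L - max_gaps], params, max_gaps
            )
            if s <= cutoff:
                out.append((o, L - max_gaps, s))
    return out


def predict_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    max_gaps: int = 1,
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Scan all transcript windows for miRNA target sites.

    Reports every site with expectation <= ``cutoff``; overlapping sites
    of the same (miRNA, transcript) pair collapse to the minimum-
    expectation one. Site coordinates are 1-based on the transcript.
    """
    if max_gaps not in (0, 1):
        raise ValueError("the window scan searches the <=1-gap space only")
    params = params or DEFAULT_PARAMS
    if not mirnas or not transcripts:
        logger.warning("empty miRNA or transcript input; no hits")
        return pd.DataFrame(columns=HIT_COLUMNS)

    rows = []
    for mid, mseq_raw in mirnas.items():
        mseq = _normalize(mseq_raw, mid)
        for tid, tseq_raw in transcripts.items():
            tseq = _normalize(tseq_raw, tid)
            if len(tseq) < len(mseq) - max_gaps:
                raise ValueError(
                    f"transcript {tid} ({len(tseq)} nt) shorter than miRNA "
                    f"{mid} ({len(mseq)} nt) minus gap budget"
                )
            placements = _scan_one(mseq, tseq, params, max_gaps, cutoff)
            placements.sort(key=lambda p: (p[2], p[0], p[1]))
            kept: list[tuple[int, int, float]] = []
            for o, lw, s in placements:
                if any(o < ko + klw and ko < o + lw for ko, klw, _ in kept):
                    continue
                kept.append((o, lw, s))
            for o, lw, s in sorted(kept):
                expect, aln, seed_mm = score_duplex(
                    mseq, tseq[o : o + lw], params, max_gaps
                )
                rows.append(
                    (mid, tid, expect, o + 1, o + lw, seed_mm,
                     _central_mismatch(aln), *aln)
                )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def pair_mirna_mr(
    hits: pd.DataFrame,
    mirna_results: pd.DataFrame,
    mr_results: pd.DataFrame,
    mode: str,
) -> pd.DataFrame:
    """Pair differential miRNAs with differential MRs they are predicted to target.

    ``mode`` is 'expression' (DEmiR x DEMR, fold-change evidence) or
    'interaction' (DImiR x DIMR, network-degree evidence). Both result
    tables are restricted to passed calls for matching stage and case
    sample; a pair is kept for every qualifying target hit, with
    ``opposite`` true when the two directions differ (the
    expression-mode pattern of interest). Same-direction pairs are
    retained and flagged.
    """
    if mode not in ("expression", "interaction"):
        raise ValueError("mode must be 'expression' or 'interaction'")
    method = "Fold change" if mode == "expression" else "SSN"
    mi = mirna_results.loc[mirna_results["passed"]]
    mr = mr_results.loc[mr_results["passed"]]
    rows = []
    for _, h in hits.iterrows():
        mi_rows = mi.loc[mi["molecule_id"] == h["mirna_id"]]
        mr_rows = mr.loc[mr["molecule_id"] == h["transcript_id"]]
        for _, a in mi_rows.iterrows():
            b_match = mr_rows.loc[
                (mr_rows["stage"] == a["stage"])
                & (mr_rows["case_sample"] == a["case_sample"])
            ]
            for _, b in b_match.iterrows():
                rows.append(
                    {
                        "mirna_id": h["mirna_id"],
                        "mr_gene_id": h["transcript_id"],
                        "stage": a["stage"],
                        "case_sample": a["case_sample"],
                        "method": method,
                        "expectation": float(h["expectation"]),
                        "mirna_direction": a["direction"],
                        "mr_direction": b["direction"],
                        "opposite": a["direction"] != b["direction"],
                        "evidence_layer": mode,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "mr_gene_id", "stage", "case_sample", "method",
            "expectation", "mirna_direction", "mr_direction", "opposite",
            "evidence_layer",
        ],
    )
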