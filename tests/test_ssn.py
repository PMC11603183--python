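"""LIONESS networks, degrees, and degree-differential tests."""

import math

import numpy as np
import pandas as pd
import pytest

from lunarice.diffexpr import ExpressionMatrix
from lunarice.ssn import (
    Network,
    aggregate_network,
    build_degree_vectors,
    degree_diff_test,
    lioness_networks,
    node_degrees,
)
from conftest import make_matrix


def meta_for(samples):
    rows = []
    for s in samples:
        stage = "tillering" if s.startswith("T") else "heading"
        group = "control" if "C" in s else "flight"
        rows.append({"sample_id": s, "group": group, "stage": stage,
                     "individual": int(s[-1])})
    return pd.DataFrame(rows)


def random_matrix(rng, n_mol, samples):
    vals = pd.DataFrame(
        rng.lognormal(3, 1, size=(n_mol, len(samples))),
        index=[f"m{i}" for i in range(n_mol)],
        columns=samples,
    )
    return ExpressionMatrix(vals, meta_for(samples))


SAMPLES12 = ["TC1", "TC2", "TC3", "TS1", "TS2", "TS3",
             "HC1", "HC2", "HC3", "HS1", "HS2", "HS3"]


def brute_force_pearson(x):
    """Textbook Pearson between rows, written without np.corrcoef."""
    n = x.shape[1]
    out = np.zeros((x.shape[0], x.shape[0]))
    for i in range(x.shape[0]):
        for j in range(x.shape[0]):
            xi = x[i] - x[i].mean()
            xj = x[j] - x[j].mean()
            denom = math.sqrt((xi**2).sum() * (xj**2).sum())
            out[i, j] = (xi * xj).sum() / denom if denom else np.nan
    return out


def brute_force_lioness(values, samples):
    """Independent leave-one-out construction of every sample network."""
    x = np.log2(values[samples].to_numpy() + 1.0)
    n = len(samples)
    full = brute_force_pearson(x)
    np.fill_diagonal(full, 0.0)
    nets = {}
    for qi, q in enumerate(samples):
        loo = brute_force_pearson(np.delete(x, qi, axis=1))
        np.fill_diagonal(loo, 0.0)
        nets[q] = n * full - (n - 1) * loo
    return nets


# -- aggregate ---------------------------------------------------------------

def test_proportional_rows_have_unit_correlation():
    samples = SAMPLES12[:6]
    base = np.array([1.0, 2.0, 4.0, 8.0, 3.0, 5.0])
    vals = pd.DataFrame(
        {s: v for s, v in zip(samples, np.column_stack([base, base * 2]).T)},
    )
    vals = pd.DataFrame(
        np.vstack([2.0**base - 1, 2.0 ** (2 * base) - 1]),
        index=["a", "b"], columns=samples,
    )  # log2(x+1) makes the rows exactly proportional
    m = ExpressionMatrix(vals, meta_for(samples))
    net = aggregate_network(m)
    assert net.weights[0, 1] == pytest.approx(1.0)
    assert net.weights[0, 0] == 0.0


def test_anticorrelated_rows_have_minus_one():
    samples = SAMPLES12[:6]
    base = np.array([1.0, 2.0, 4.0, 8.0, 3.0, 5.0])
    vals = pd.DataFrame(
        np.vstack([2.0**base - 1, 2.0 ** (10 - base) - 1]),
        index=["a", "b"], columns=samples,
    )
    m = ExpressionMatrix(vals, meta_for(samples))
    assert aggregate_network(m).weights[0, 1] == pytest.approx(-1.0)


def test_aggregate_matches_textbook_pearson(rng):
    m = random_matrix(rng, 20, SAMPLES12[:8])
    net = aggregate_network(m)
    want = brute_force_pearson(np.log2(m.values.to_numpy() + 1.0))
    np.fill_diagonal(want, 0.0)
    assert np.max(np.abs(net.weights - want)) < 1e-12


def test_aggregate_excludes_constant_rows(rng):
    m = random_matrix(rng, 10, SAMPLES12[:6])
    m.values.loc["m0"] = 7.0
    net = aggregate_network(m)
    assert net.excluded == ["m0"]
    assert "m0" not in net.node_ids


def test_aggregate_needs_three_samples(rng):
    with pytest.raises(ValueError):
        aggregate_network(random_matrix(rng, 5, SAMPLES12[:2]))


# -- LIONESS -----------------------------------------------------------------

def test_lioness_equals_brute_force_leave_one_out(rng):
    m = random_matrix(rng, 15, SAMPLES12[:8])
    nets = lioness_networks(m)
    want = brute_force_lioness(m.values, SAMPLES12[:8])
    for q in SAMPLES12[:8]:
        assert np.max(np.abs(nets[q].weights - want[q])) < 1e-10


def test_lioness_identity_when_loo_leaves_correlations_unchanged():
    # rows exactly linear in one latent profile: every subset of >=3 samples
    # gives the same (unit) correlations, so e_q = N*c - (N-1)*c = c
    samples = SAMPLES12[:6]
    base = np.array([1.0, 2.0, 4.0, 8.0, 3.0, 5.0])
    vals = pd.DataFrame(
        np.vstack([2.0 ** (a + b * base) - 1 for a, b in
                   [(0, 1), (1, 0.5), (2, 0.25)]]),
        index=["a", "b", "c"], columns=samples,
    )
    m = ExpressionMatrix(vals, meta_for(samples))
    agg = aggregate_network(m)
    nets = lioness_networks(m)
    for q in samples:
        assert np.max(np.abs(nets[q].weights - agg.weights)) < 1e-9


def test_lioness_minimal_four_samples(rng):
    nets = lioness_networks(random_matrix(rng, 6, SAMPLES12[:4]))
    assert len(nets) == 4
    with pytest.raises(ValueError):
        lioness_networks(random_matrix(rng, 6, SAMPLES12[:3]))


def test_lioness_invariant_to_sample_permutation(rng):
    m = random_matrix(rng, 12, SAMPLES12[:6])
    nets = lioness_networks(m, SAMPLES12[:6])
    shuffled = ExpressionMatrix(
        m.values[["TS3", "TC1", "TS1", "TC3", "TC2", "TS2"]], m.sample_meta
    )
    nets2 = lioness_networks(shuffled, SAMPLES12[:6])
    for q in SAMPLES12[:6]:
        assert np.max(np.abs(nets[q].weights - nets2[q].weights)) < 1e-12


# -- degrees -----------------------------------------------------------------

def _net(w, nodes, sample="TS1"):
    return Network(node_ids=nodes, weights=np.asarray(w, dtype=float),
                   estimator="test", samples=[], sample_id=sample)


def test_complete_graph_degrees():
    w = np.full((4, 4), 0.95)
    np.fill_diagonal(w, 0.0)
    deg = node_degrees(_net(w, list("abcd")), tau=0.8)
    assert (deg == 3).all()


def test_tau_above_max_weight_gives_zero_degrees():
    w = np.full((4, 4), 0.5)
    np.fill_diagonal(w, 0.0)
    assert (node_degrees(_net(w, list("abcd")), tau=0.8) == 0).all()


def test_degrees_match_enumeration(rng):
    w = rng.normal(0, 1, size=(10, 10))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    deg = node_degrees(_net(w, [f"n{i}" for i in range(10)]), tau=0.8)
    for i in range(10):
        expected = sum(1 for j in range(10) if j != i and abs(w[i, j]) >= 0.8)
        assert deg.iloc[i] == expected


def test_degree_vectors_have_one_entry_per_network(rng):
    m = random_matrix(rng, 10, SAMPLES12)
    nets = lioness_networks(m)
    dv = build_degree_vectors(nets, SAMPLES12, tau=0.8)
    assert list(dv.columns) == SAMPLES12 and dv.shape[1] == 12
    # entries agree with per-network degrees
    for s in SAMPLES12[:3]:
        deg = node_degrees(nets[s], 0.8)
        assert (dv.loc[deg.index, s] == deg).all()


def test_excluded_molecule_gets_zero_degrees(rng):
    m = random_matrix(rng, 8, SAMPLES12)
    m.values.loc["m0"] = 3.0  # constant: excluded from every network
    nets = lioness_networks(m)
    dv = build_degree_vectors(nets, SAMPLES12, tau=0.8)
    assert (dv.loc["m0"] == 0).all()


# -- degree-differential test ------------------------------------------------

def degree_frame(d_rows, samples=SAMPLES12):
    return pd.DataFrame(d_rows, columns=samples)


def test_degree_diff_symmetric_case():
    dv = pd.DataFrame([[5, 6, 7, 6] + [0] * 8], index=["g1"], columns=SAMPLES12)
    res = degree_diff_test(dv, meta_for(SAMPLES12), "tillering", "TS1")
    assert res.iloc[0]["p_value"] == pytest.approx(1.0)
    assert not res.iloc[0]["passed"]


def test_degree_diff_zero_variance_diagnostic():
    dv = pd.DataFrame([[5, 5, 5, 9] + [0] * 8], index=["g1"], columns=SAMPLES12)
    res = degree_diff_test(dv, meta_for(SAMPLES12), "tillering", "TS1")
    assert res.iloc[0]["note"] == "zero_variance"
    assert not res.iloc[0]["passed"]


def test_degree_diff_matches_closed_form_df2():
    dv = pd.DataFrame([[2, 4, 6, 12] + [0] * 8], index=["g1"], columns=SAMPLES12)
    res = degree_diff_test(dv, meta_for(SAMPLES12), "tillering", "TS1")
    x = np.array([2.0, 4.0, 6.0])
    t = (x.mean() - 12.0) / (x.std(ddof=1) / math.sqrt(3))
    p_closed = 1.0 - abs(t) / math.sqrt(2.0 + t * t)
    assert res.iloc[0]["p_value"] == pytest.approx(p_closed, abs=1e-12)
    assert res.iloc[0]["direction"] == "up"


def test_degree_diff_unknown_case_sample():
    dv = pd.DataFrame([[1] * 12], index=["g1"], columns=SAMPLES12)
    with pytest.raises(KeyError):
        degree_diff_test(dv, meta_for(SAMPLES12), "tillering", "XX9")
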