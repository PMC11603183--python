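"""LIONESS single-sample co-expression networks and degree-differential tests.

An aggregate network is the pairwise Pearson correlation (on log2(x+1))
of molecules over a sample set. LIONESS extracts one network per sample by
linear interpolation between the aggregate and its leave-one-out
counterpart:

    e_q = N * e_all - (N - 1) * e_all_without_q

Node degrees are neighbor counts after binarizing edges at |weight| >= tau
(LIONESS weights can leave [-1, 1], so tau applies to the edge value
itself). Each molecule's degrees across all n sample networks form its
degree vector d = (d1, ..., dn), with d_i = 0 when the molecule was
excluded from the i-th network. A flight individual's degree d_SP is then
compared against the three stage-matched control degrees d_GC = (d1, d2,
d3) with a two-sided one-sample t-test (df = 2); molecules with p < 0.05
are differentially interacting (DIGs for mRNA, DImiRs for miRNA).

mRNA and miRNA networks are built independently; there are no cross-layer
edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import one_sample_t
from .diffexpr import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.8


@dataclass
class Network:
    """A weighted co-expression network over a fixed node set.

    ``weights`` is symmetric with zero diagonal; ``excluded`` lists
    molecules dropped for zero variance (they keep degree 0 downstream).
    """

    node_ids: list[str]
    weights: np.ndarray
    estimator: str
    samples: list[str]
    excluded: list[str] = field(default_factory=list)
    sample_id: str | None = None


def _log_transform(values: pd.DataFrame) -> pd.DataFrame:
    return np.log2(values + 1.0)


def _corr(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; constant rows yield nan."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    return c


def aggregate_network(
    matrix: ExpressionMatrix,
    sample_set: list[str] | None = None,
    method: str = "pearson",
) -> Network:
    """Aggregate co-expression network over ``sample_set``.

    Pearson (default) or Spearman correlation of log2(x+1) rows; rows
    constant over the sample set are excluded with a warning and listed
    in ``excluded``. Diagonal is forced to 0.
    """
    samples = sample_set or list(matrix.values.columns)
    if len(samples) < 3:
        raise ValueError("aggregate network needs >=3 samples")
    x = _log_transform(matrix.values[samples])
    var = x.var(axis=1, ddof=0)
    excluded = list(x.index[var == 0])
    if excluded:
        logger.warning("excluding %d zero-variance molecules", len(excluded))
    x = x.loc[var > 0]
    data = x.to_numpy()
    if method == "spearman":
        data = np.apply_along_axis(stats.rankdata, 1, data)
    w = _corr(data)
    np.fill_diagonal(w, 0.0)
    return Network(
        node_ids=list(x.index),
        weights=w,
        estimator=method,
        samples=list(samples),
        excluded=excluded,
    )


def lioness_networks(
    matrix: ExpressionMatrix,
    sample_set: list[str] | None = None,
    method: str = "pearson",
) -> dict[str, Network]:
    """One LIONESS network per sample: e_q = N*e_all - (N-1)*e_all\\{q}.

    Requires N >= 4 samples (the leave-one-out network needs >= 3). Edges
    involving a node whose leave-one-out row is constant are set to 0 for
    that sample's network, mirroring the aggregate's excluded-node
    treatment.
    """
    samples = sample_set or list(matrix.values.columns)
    n = len(samples)
    if n < 4:
        raise ValueError(f"LIONESS needs >=4 samples, got {n}")
    agg = aggregate_network(matrix, samples, method=method)
    x = _log_transform(matrix.values.loc[agg.node_ids, samples])
    data = x.to_numpy()
    if method == "spearman":
        full = np.apply_along_axis(stats.rankdata, 1, data)
    out: dict[str, Network] = {}
    for qi, q in enumerate(samples):
        loo_cols = [j for j in range(n) if j != qi]
        sub = data[:, loo_cols]
        if method == "spearman":
            sub = np.apply_along_axis(stats.rankdata, 1, sub)
        w_loo = _corr(sub)
        np.fill_diagonal(w_loo, 0.0)
        dropped = ~np.isfinite(w_loo).all(axis=1)
        w_loo = np.nan_to_num(w_loo, nan=0.0)
        e_q = n * agg.weights - (n - 1) * w_loo
        if dropped.any():
            e_q[dropped, :] = 0.0
            e_q[:, dropped] = 0.0
            logger.warning(
                "sample %s: %d nodes constant after leave-one-out; edges zeroed",
                q, int(dropped.sum()),
            )
        out[q] = Network(
            node_ids=agg.node_ids,
            weights=e_q,
            estimator=f"lioness-{method}",
            samples=[s for s in samples if s != q],
            excluded=agg.excluded,
            sample_id=q,
        )
    return out


def node_degrees(network: Network, tau: float = DEFAULT_TAU) -> pd.Series:
    """Degree of each node: count of partners with |edge weight| >= tau."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    adj = np.abs(network.weights) >= tau
    np.fill_diagonal(adj, False)
    return pd.Series(adj.sum(axis=1), index=network.node_ids, name="degree")


def build_degree_vectors(
    networks: dict[str, Network],
    sample_order: list[str],
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Degree vectors d = (d1..dn) over networks in canonical sample order.

    The node universe is the union over networks; a molecule absent from
    (or excluded in) a network gets degree 0 there.
    """
    universe: list[str] = []
    seen = set()
    for s in sample_order:
        for node in networks[s].node_ids + networks[s].excluded:
            if node not in seen:
                seen.add(node)
                universe.append(node)
    df = pd.DataFrame(0, index=universe, columns=sample_order, dtype=int)
    for s in sample_order:
        deg = node_degrees(networks[s], tau)
        df.loc[deg.index, s] = deg.to_numpy()
    return df


DEGREE_DIFF_COLUMNS = [
    "molecule_id", "stage", "case_sample",
    "d_gc", "d_sp", "p_value", "direction", "passed", "note",
]


def degree_diff_test(
    degree_vectors: pd.DataFrame,
    sample_meta: pd.DataFrame,
    stage: str,
    case_sample: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Degree-differential test for one flight individual at one stage.

    d_GC is the molecule's degree triple in the stage-matched control
    networks; d_SP its degree in the case network. p is the two-sided
    one-sample t-test of d_GC against d_SP as hypothesized mean;
    molecules with p < 0.05 pass (DIGs / DImiRs). Zero-variance control
    triples are routed to diagnostics via the note column.
    """
    if case_sample not in degree_vectors.columns:
        raise KeyError(f"case sample {case_sample!r} has no degree column")
    m = sample_meta
    ctrl = [
        s
        for s in degree_vectors.columns
        if s in set(m.loc[(m["stage"] == stage) & (m["group"] == "control"), "sample_id"])
    ]
    if not ctrl:
        raise ValueError(f"no control samples for stage {stage!r}")
    rows = []
    d_gc_all = degree_vectors[ctrl].to_numpy()
    d_sp_all = degree_vectors[case_sample].to_numpy()
    for i, mol in enumerate(degree_vectors.index):
        d_gc = d_gc_all[i]
        d_sp = d_sp_all[i]
        _, p, note = one_sample_t(d_gc, d_sp)
        passed = (note == "") and (p < alpha)
        direction = "up" if d_sp >= d_gc.mean() else "down"
        rows.append(
            (mol, stage, case_sample,
             ",".join(f"{v:g}" for v in d_gc), float(d_sp), p, direction,
             bool(passed), note)
        )
    return pd.DataFrame(rows, columns=DEGREE_DIFF_COLUMNS)
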