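"""Group and single-sample differential expression.

Expression lives in an :class:`ExpressionMatrix` (molecules x samples plus a
sample sheet with group/stage/individual). Three callers are provided:

* ``deg_group`` — classic 3-vs-3 comparison per stage (Welch t on
  log2(x+1), fold-change computed on means), gated at |log2FC| > 1 and
  p < 0.05;
* ``deg_single_sample`` — one flight individual against its three
  stage-matched ground controls: a two-sided one-sample t-test of the
  control triple with the case value as the hypothesized mean (df = 2),
  same |log2FC| > 1 and p < 0.05 gates;
* ``demir_demr_single`` — the same statistic for miRNAs and for DNA
  methylation regulatory factors (MRs), where only p < 0.05 is required
  (no fold-change gate).

Molecules with zero expression across every sample of a comparison side are
removed first; zero-variance control triples are routed to a diagnostics
note instead of receiving a p-value.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import one_sample_t
from scipy import stats

DIFF_COLUMNS = [
    "molecule_id", "layer", "method", "stage", "case_sample",
    "log2fc", "p_value", "direction", "passed", "note",
]

#: pseudo-count on the FPKM/TPM scale used in fold changes
DEFAULT_EPS = 0.01


@dataclass
class ExpressionMatrix:
    """Molecules x samples abundance table with sample metadata.

    ``values`` is a DataFrame indexed by molecule id with one column per
    sample; ``sample_meta`` has columns sample_id, group (control/flight),
    stage, individual.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate molecule ids: {dup[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.values.columns) - set(self.sample_meta["sample_id"])
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")

    def samples(self, stage: str, group: str) -> list[str]:
        m = self.sample_meta
        sel = m.loc[(m["stage"] == stage) & (m["group"] == group), "sample_id"]
        return [s for s in self.values.columns if s in set(sel)]

    def subset(self, molecule_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[molecule_ids], self.sample_meta)


def load_mr_catalog() -> pd.DataFrame:
    """The packaged catalog of DNA methylation regulatory factors.

    Methyltransferases, RdDM-pathway components, demethylases and the
    methyl-donor-cycle enzyme, keyed by rice gene id.
    """
    ref = importlib.resources.files("lunarice").joinpath("data/mr_catalog.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def filter_zero_expression(
    matrix: ExpressionMatrix,
    side_a: list[str],
    side_b: list[str],
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop molecules with zero expression across every sample of a side.

    A molecule survives only if it is non-zero in at least one sample of
    each comparison side. Returns the filtered matrix and a removal report
    (molecule_id, reason).
    """
    if not side_a or not side_b:
        raise ValueError("both comparison sides must be non-empty")
    va = matrix.values[side_a]
    vb = matrix.values[side_b]
    zero_a = (va == 0).all(axis=1)
    zero_b = (vb == 0).all(axis=1)
    removed = zero_a | zero_b
    report = pd.DataFrame(
        {
            "molecule_id": matrix.values.index[removed],
            "reason": np.where(
                zero_a[removed] & zero_b[removed],
                "zero_both_sides",
                np.where(zero_a[removed], "zero_in_side_a", "zero_in_side_b"),
            ),
        }
    )
    kept = ExpressionMatrix(matrix.values.loc[~removed], matrix.sample_meta)
    return kept, report


def _log2fc(case_mean: np.ndarray, ctrl_mean: np.ndarray, eps: float) -> np.ndarray:
    return np.log2((case_mean + eps) / (ctrl_mean + eps))


def deg_group(
    matrix: ExpressionMatrix,
    stage: str,
    layer: str = "mRNA",
    alpha: float = 0.05,
    lfc_gate: float = 1.0,
    eps: float = DEFAULT_EPS,
    require_fold_change: bool = True,
) -> pd.DataFrame:
    """Group-mode differential expression (flight vs control) for one stage.

    Welch two-sample t-test on log2(x+1); log2 fold change from side means
    with an ``eps`` pseudo-count; passes at |log2FC| > 1 (strict) and
    p < 0.05. For the MR layer set ``require_fold_change=False``.
    """
    ctrl = matrix.samples(stage, "control")
    case = matrix.samples(stage, "flight")
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("group mode needs >=2 samples per side")
    matrix, _ = filter_zero_expression(matrix, ctrl, case)
    xc = np.log2(matrix.values[ctrl].to_numpy() + 1.0)
    xs = np.log2(matrix.values[case].to_numpy() + 1.0)
    t, p = stats.ttest_ind(xs, xc, axis=1, equal_var=False)
    lfc = _log2fc(
        matrix.values[case].mean(axis=1).to_numpy(),
        matrix.values[ctrl].mean(axis=1).to_numpy(),
        eps,
    )
    passed = (p < alpha) & (np.abs(lfc) > lfc_gate if require_fold_change else True)
    return pd.DataFrame(
        {
            "molecule_id": matrix.values.index,
            "layer": layer,
            "method": "group-welch",
            "stage": stage,
            "case_sample": "group",
            "log2fc": lfc,
            "p_value": p,
            "direction": np.where(lfc >= 0, "up", "down"),
            "passed": passed,
            "note": "",
        },
        columns=DIFF_COLUMNS,
    ).reset_index(drop=True)


def _single_sample_frame(
    matrix: ExpressionMatrix,
    stage: str,
    case_sample: str,
    layer: str,
    alpha: float,
    lfc_gate: float | None,
    eps: float,
) -> pd.DataFrame:
    ctrl = matrix.samples(stage, "control")
    if case_sample not in matrix.values.columns:
        raise KeyError(f"case sample {case_sample!r} not in matrix")
    if not ctrl:
        raise ValueError(f"no control samples for stage {stage!r}")
    matrix, _ = filter_zero_expression(matrix, ctrl, [case_sample])
    vals = matrix.values
    rows = []
    for mol, row in vals.iterrows():
        controls = row[ctrl].to_numpy(dtype=float)
        case = float(row[case_sample])
        _, p, note = one_sample_t(controls, case)
        lfc = float(_log2fc(np.array(case), controls.mean(), eps))
        gate_ok = True if lfc_gate is None else abs(lfc) > lfc_gate
        passed = (note == "") and (p < alpha) and gate_ok
        rows.append(
            (mol, layer, "single_sample", stage, case_sample,
             lfc, p, "up" if lfc >= 0 else "down", bool(passed), note)
        )
    return pd.DataFrame(rows, columns=DIFF_COLUMNS)


def deg_single_sample(
    matrix: ExpressionMatrix,
    stage: str,
    case_sample: str,
    layer: str = "mRNA",
    alpha: float = 0.05,
    lfc_gate: float | None = 1.0,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Single-sample DEGs: one flight plant against the 3 stage controls.

    p is the two-sided one-sample t-test of the control values with the
    case value as hypothesized mean (df = 2, as in scipy's ttest_1samp);
    passes at |log2FC| > 1 and p < 0.05. Zero-variance control triples
    carry a ``zero_variance`` note, never a pass.
    """
    return _single_sample_frame(
        matrix, stage, case_sample, layer, alpha, lfc_gate, eps
    )


def demir_demr_single(
    matrix: ExpressionMatrix,
    layer: str,
    stage: str,
    case_sample: str,
    mr_catalog: pd.DataFrame | None = None,
    alpha: float = 0.05,
    eps: float = DEFAULT_EPS,
) -> tuple[pd.DataFrame, list[str]]:
    """Single-sample DEmiRs / DEMRs: same statistic, p < 0.05 only.

    For ``layer='MR'`` the matrix is restricted to catalog gene ids; ids
    missing from the matrix are returned as a coverage warning list.
    """
    missing: list[str] = []
    if layer == "MR":
        catalog = mr_catalog if mr_catalog is not None else load_mr_catalog()
        ids = [g for g in catalog["gene_id"] if g in matrix.values.index]
        missing = [g for g in catalog["gene_id"] if g not in matrix.values.index]
        matrix = matrix.subset(ids)
    res = _single_sample_frame(
        matrix, stage, case_sample, layer, alpha, lfc_gate=None, eps=eps
    )
    return res, missing


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method from four Ct values."""
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
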