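"""Shared statistical primitives.

Small, vectorised building blocks used by the methylome and integration
modules: an exact two-sided Fisher test for many 2x2 tables at once, the
Stouffer z combination for merging per-site evidence into region-level
p-values, and the one-sample t-test wrapper (with explicit zero-variance
routing) that every single-sample comparison in the package goes through.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# Relative slack when collecting "as or more extreme" outcomes; matches the
# convention of mainstream implementations so exact oracles agree bitwise.
_RELATIVE_ERR = 1.0 + 1e-7


def fisher_exact_two_sided(a, b, c, d) -> np.ndarray:
    """Exact two-sided Fisher p-values for vectors of 2x2 tables.

    Tables are ``[[a, b], [c, d]]``. The two-sided p-value sums the
    hypergeometric probabilities of every outcome whose probability does
    not exceed that of the observed table (to within a 1e-7 relative
    slack). Implemented by enumerating the support of each table's
    hypergeometric distribution, so it is exact for any margins.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("2x2 table entries must be non-negative")

    n = a + b + c + d          # total
    r1 = a + b                 # first row margin
    c1 = a + c                 # first column margin
    lo = np.maximum(0, r1 + c1 - n)
    hi = np.minimum(r1, c1)

    width = int(np.max(hi - lo, initial=0)) + 1
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    k_safe = np.where(valid, k, lo[:, None])

    pmf = stats.hypergeom.pmf(k_safe, n[:, None], c1[:, None], r1[:, None])
    pmf = np.where(valid, pmf, 0.0)
    obs = stats.hypergeom.pmf(a, n, c1, r1)

    take = pmf <= obs[:, None] * _RELATIVE_ERR
    p = np.sum(np.where(take, pmf, 0.0), axis=1)
    return np.minimum(p, 1.0)


def stouffer_combine(p_values: np.ndarray, signs: np.ndarray) -> float:
    """Combine per-site two-sided p-values into one two-sided p.

    Each site contributes a signed z-score ``sign * Phi^-1(1 - p/2)``;
    the combined statistic is their mean scaled by sqrt(k). Used for
    region p-values where all contributing sites share a direction.
    """
    p = np.asarray(p_values, dtype=float)
    s = np.asarray(signs, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty set of p-values")
    # Guard against p == 0 from underflow; isf keeps precision for tiny p.
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0) * s
    z_comb = z.sum() / np.sqrt(p.size)
    return float(2.0 * stats.norm.sf(abs(z_comb)))


def one_sample_t(values: np.ndarray, popmean: float) -> tuple[float, float, str]:
    """Two-sided one-sample t-test of ``values`` against ``popmean``.

    Returns ``(t, p, note)``. A zero-variance sample cannot be tested:
    the statistic is undefined and the result is routed to diagnostics
    with ``note='zero_variance'`` and ``p = nan`` rather than being
    reported significant (or not) by fiat.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test needs at least 2 observations")
    if np.ptp(x) == 0.0:
        return float("nan"), float("nan"), "zero_variance"
    t, p = stats.ttest_1samp(x, popmean)
    return float(t), float(p), ""
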