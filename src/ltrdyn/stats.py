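"""Shared statistical primitives: Mann-Whitney U, Fisher exact, BH-FDR.

The Mann-Whitney implementation uses exact enumeration of group assignments
for small samples (both groups <= ``EXACT_N``), which handles ties correctly,
and the tie-corrected normal approximation otherwise.
"""
from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

EXACT_N = 8


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a``: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U computed for the first sample. Exact for
    n <= 8 per group (full enumeration over group assignments, tie-safe);
    tie-corrected normal approximation with continuity correction otherwise.

    Raises ``ValueError`` on an empty sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n * m / 2.0

    if n <= EXACT_N and m <= EXACT_N:
        pooled = np.concatenate([a, b])
        idx = range(n + m)
        total = comb(n + m, n)
        dev_obs = abs(u_obs - mu)
        hits = 0
        for pick in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total

    pooled = np.concatenate([a, b])
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * _st.norm.sf(z)
    return u_obs, min(p, 1.0)


def fisher_exact_test(n11: int, n12: int, n21: int, n22: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table; returns (odds ratio, p)."""
    for v in (n11, n12, n21, n22):
        if v < 0:
            raise ValueError("contingency cells must be non-negative")
    odds, p = _st.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return float(odds), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate as NaN)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
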