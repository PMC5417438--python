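"""Monte-Carlo simulated chi-squared test of independence on a 2xn table.

This is the distribution criterion of the earlier distribution-based
callers, retained here as the gold-standard oracle for evaluating the
likelihood-ratio test. The observed statistic is the Pearson chi-squared
statistic of the 2xn table whose rows are the OTU's and the candidate's
per-sample counts; its null distribution is estimated by sampling tables
uniformly among all tables with the same row and column margins (Patefield's
algorithm, the same null as R's ``chisq.test(simulate.p.value=TRUE)``).

For tiny tables :func:`exact_pvalue` enumerates every table with the given
margins, weighting each by its multivariate hypergeometric probability —
an independent check on the sampler.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

_TIE_EPS = 1e-9  # simulated stats equal to the observed one count as >=


@dataclasses.dataclass(frozen=True)
class SimTestResult:
    statistic: float
    n_sims: int
    p_value: float
    seed: int


def _table(x1, x2) -> np.ndarray:
    tab = np.array([np.asarray(x1), np.asarray(x2)], dtype=np.int64)
    if tab.ndim != 2 or tab.shape[0] != 2:
        raise ValueError("inputs must form a 2xn table")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if tab.sum() == 0:
        raise ValueError("all-zero table")
    # zero-total columns carry no margin information; drop them
    return tab[:, tab.sum(axis=0) > 0]


def chi2_statistic(x1, x2) -> float:
    """Pearson chi-squared statistic, summed over cells with expected > 0."""
    tab = _table(x1, x2)
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    mask = expected > 0
    return float(((tab[mask] - expected[mask]) ** 2 / expected[mask]).sum())


def simulate_pvalue(x1, x2, n_sims: int = 10_000, seed: int = 0) -> SimTestResult:
    """Monte-Carlo p-value with the +1 correction: (1 + #{sim >= obs})/(B + 1).

    Samples are drawn uniformly over tables with fixed row and column
    margins; generation is chunked so that very large B stays within memory.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    tab = _table(x1, x2)
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if np.any(rows == 0):
        raise ValueError("degenerate margins: a row has zero total")
    observed = chi2_statistic(x1, x2)
    expected = np.outer(rows, cols) / tab.sum()
    sampler = stats.random_table(rows, cols)
    rng = np.random.default_rng(seed)
    exceed = 0
    remaining = n_sims
    chunk = 500_000
    while remaining > 0:
        b = min(chunk, remaining)
        sims = sampler.rvs(b, random_state=rng)
        sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        exceed += int((sim_stats >= observed - _TIE_EPS).sum())
        remaining -= b
    p = (1 + exceed) / (n_sims + 1)
    return SimTestResult(statistic=observed, n_sims=n_sims, p_value=p, seed=seed)


def _count_tables(cols: np.ndarray, total_row1: int) -> int:
    """Number of top rows a1 with 0 <= a1(j) <= cols(j) and sum = total_row1."""
    reachable = {0: 1}
    for c in cols:
        nxt: dict[int, int] = {}
        for s, ways in reachable.items():
            for a in range(0, int(c) + 1):
                if s + a <= total_row1:
                    nxt[s + a] = nxt.get(s + a, 0) + ways
        reachable = nxt
    return reachable.get(total_row1, 0)


def exact_pvalue(x1, x2, max_tables: int = 100_000) -> float:
    """Exact tail probability P(stat >= observed) under the fixed-margins null.

    Enumerates every 2xn table with the observed margins; each has
    probability prod_j C(c_j, a_j) / C(N, R1) where a_j is the top-row cell,
    c_j the column margin, R1 the top-row margin. Errors out if the
    enumeration would exceed ``max_tables``.
    """
    tab = _table(x1, x2)
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if np.any(rows == 0):
        raise ValueError("degenerate margins: a row has zero total")
    n_tables = _count_tables(cols, int(rows[0]))
    if n_tables > max_tables:
        raise ValueError(f"{n_tables} tables with these margins exceeds {max_tables}")
    observed = chi2_statistic(x1, x2)
    expected = np.outer(rows, cols) / tab.sum()
    total = int(tab.sum())
    r1 = int(rows[0])
    log_denom = math.lgamma(total + 1) - math.lgamma(r1 + 1) - math.lgamma(total - r1 + 1)

    n = len(cols)
    tail = 0.0
    top = np.zeros(n, dtype=np.int64)

    def recurse(j: int, remaining: int, log_w: float) -> None:
        nonlocal tail
        if j == n - 1:
            if remaining > cols[j]:
                return
            top[j] = remaining
            lw = log_w + (
                math.lgamma(cols[j] + 1)
                - math.lgamma(remaining + 1)
                - math.lgamma(cols[j] - remaining + 1)
            )
            bottom = cols - top
            cells = np.array([top, bottom], dtype=np.float64)
            stat = ((cells - expected) ** 2 / expected).sum()
            if stat >= observed - _TIE_EPS:
                tail += math.exp(lw - log_denom)
            return
        hi = min(int(cols[j]), remaining)
        for a in range(0, hi + 1):
            top[j] = a
            lw = log_w + (
                math.lgamma(cols[j] + 1) - math.lgamma(a + 1) - math.lgamma(cols[j] - a + 1)
            )
            recurse(j + 1, remaining - a, lw)

    recurse(0, r1, 0.0)
    return min(tail, 1.0)
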