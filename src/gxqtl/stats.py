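"""Core statistical primitives.

The centerpiece is the stratified two-degrees-of-freedom (2DF) joint test:
squared Wald ratios from disjoint exposure strata (here smoking cases and
controls) are summed into a chi-square statistic on 2 df, which is sensitive
to a genetic main effect, a genotype-by-exposure interaction, or both. The
strata are disjoint samples, so the two Wald ratios are treated as
independent and no covariance term enters.

Also provided: an exact r x c Fisher test by complete enumeration (with a
seeded Monte Carlo fallback for large tables), Welch's t test from printed
summary statistics, and a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "Stratified2dfResult",
    "stratified_2df",
    "fisher_exact",
    "welch_t_from_summary",
    "ks_two_sample",
]


@dataclass(frozen=True)
class Stratified2dfResult:
    """Result of the stratified 2DF joint test."""

    z_case: float
    z_ctrl: float
    T: float
    p_2df: float


def stratified_2df(beta_case, se_case, beta_ctrl, se_ctrl):
    """Joint 2-df chi-square test from per-stratum Wald summaries.

    ``z_s = beta_s / se_s`` per stratum; ``T = z_case**2 + z_ctrl**2`` is
    chi-square with 2 df under the joint null of no genetic effect in either
    stratum, so ``p = exp(-T/2)``.

    Accepts scalars or arrays (broadcast elementwise). NaN inputs (a failed
    stratum fit) propagate to a NaN statistic and p-value; there is no
    fallback to a 1-df test.

    Returns
    -------
    Stratified2dfResult for scalar input, otherwise a tuple ``(T, p)`` of
    arrays.
    """
    beta_case = np.asarray(beta_case, dtype=float)
    se_case = np.asarray(se_case, dtype=float)
    beta_ctrl = np.asarray(beta_ctrl, dtype=float)
    se_ctrl = np.asarray(se_ctrl, dtype=float)
    for se in (se_case, se_ctrl):
        bad = se[np.isfinite(se)] <= 0
        if np.any(bad):
            raise ValueError("standard errors must be > 0")
    z_case = beta_case / se_case
    z_ctrl = beta_ctrl / se_ctrl
    T = z_case**2 + z_ctrl**2
    # chi2(2) survival function has the closed form exp(-T/2)
    p = np.exp(-T / 2.0)
    if T.ndim == 0:
        return Stratified2dfResult(float(z_case), float(z_ctrl), float(T), float(p))
    return T, p


def _log_table_prob(table: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray, n: int) -> float:
    # multivariate hypergeometric probability of an r x c table given margins
    lp = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )
    return float(lp)


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r = len(row_sums)

    def rec(i, remaining_cols, rows_out):
        if i == r - 1:
            last = remaining_cols
            if np.all(last >= 0) and last.sum() == row_sums[i]:
                yield np.array(rows_out + [last])
            return
        # enumerate row i summing to row_sums[i], bounded by remaining cols
        for row in _compositions(row_sums[i], remaining_cols):
            yield from rec(i + 1, remaining_cols - row, rows_out + [row])

    yield from rec(0, np.array(col_sums, dtype=int), [])


def _compositions(total, caps):
    """All non-negative integer vectors <= caps elementwise summing to total."""
    c = len(caps)
    if c == 1:
        if 0 <= total <= caps[0]:
            yield np.array([total])
        return
    lo = max(0, total - int(caps[1:].sum()))
    hi = min(int(caps[0]), total)
    for v in range(lo, hi + 1):
        for rest in _compositions(total - v, caps[1:]):
            yield np.concatenate(([v], rest))


def fisher_exact(table, *, max_tables: int = 2_000_000, n_mc: int = 100_000, seed: int | None = None) -> float:
    """Two-sided Fisher exact test for an r x c contingency table.

    Uses the minimum-likelihood convention: the p-value sums the
    (multivariate) hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed that of the observed
    table (with a small relative tolerance, matching R's ``fisher.test``).

    For tables whose margin space exceeds ``max_tables`` an exact enumeration
    is refused; pass a ``seed`` to fall back to seeded Monte Carlo sampling
    of tables from the margin-conditional null instead.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(table < 0):
        raise ValueError("table entries must be non-negative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("all row and column margins must be positive")
    n = int(table.sum())

    lp_obs = _log_table_prob(table, row_sums, col_sums, n)
    tol = 1e-7  # relative tolerance on probabilities, as in R

    # crude upper bound on the number of tables to enumerate
    bound = 1.0
    for rs in row_sums[:-1]:
        for cs in col_sums[:-1]:
            bound *= min(rs, cs) + 1
            if bound > max_tables:
                break
        if bound > max_tables:
            break
    if bound > max_tables:
        if seed is None:
            raise ValueError(
                "table too large for complete enumeration; pass seed= to use "
                "the Monte Carlo mode"
            )
        return _fisher_mc(table, row_sums, col_sums, n, lp_obs, tol, n_mc, seed)

    log_num = []
    log_all = []
    for t in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(t, row_sums, col_sums, n)
        log_all.append(lp)
        if lp <= lp_obs + tol:
            log_num.append(lp)
    total = np.logaddexp.reduce(log_all)
    p = float(np.exp(np.logaddexp.reduce(log_num) - total))
    return min(p, 1.0)


def _fisher_mc(table, row_sums, col_sums, n, lp_obs, tol, n_mc, seed) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        t = _random_table(row_sums, col_sums, rng)
        if _log_table_prob(t, row_sums, col_sums, n) <= lp_obs + tol:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def _random_table(row_sums, col_sums, rng):
    # sample from the margin-conditional null by permutation
    labels = np.repeat(np.arange(len(col_sums)), col_sums)
    rng.shuffle(labels)
    t = np.zeros((len(row_sums), len(col_sums)), dtype=int)
    start = 0
    for i, rs in enumerate(row_sums):
        seg = labels[start : start + rs]
        t[i] = np.bincount(seg, minlength=len(col_sums))
        start += rs
    return t


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's unequal-variance t test from group summaries.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p-value.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


def ks_two_sample(x, y, mode: str = "asymptotic"):
    """Two-sided two-sample Kolmogorov-Smirnov test.

    ``D`` is the supremum distance between the two empirical CDFs. The
    asymptotic p uses the Kolmogorov distribution at the effective sample
    size n*m/(n+m); ``mode='exact'`` computes the exact permutation null
    (suitable for small samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    method = {"asymptotic": "asymp", "exact": "exact"}[mode]
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
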