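"""Nonparametric between-cluster comparisons.

Continuous/ordinal variables are compared across the k affective profiles
with tie-corrected Kruskal-Wallis tests; the effect size is the rank
eta-squared ``(H - k + 1) / (n - k)`` (clipped below at 0). Significant
omnibus tests are followed by pairwise two-sample rank-sum (Mann-Whitney)
tests with Bonferroni adjustment over the k(k-1)/2 pairs. Categorical
variables use an r x c Fisher exact test (full enumeration of the
fixed-margins table space where feasible, otherwise Monte-Carlo) reported
alongside the Pearson chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "KruskalResult",
    "FisherResult",
    "eta_squared_from_h",
    "kruskal_wallis_eta2",
    "pairwise_wilcoxon_bonferroni",
    "fisher_exact_rxc",
]


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float
    eta_squared: float


@dataclass(frozen=True)
class FisherResult:
    chi2: float
    df: int
    fisher_p: float
    method: str  # "enumeration" or "monte_carlo"


def eta_squared_from_h(h: float, k: int, n: int) -> float:
    """Rank eta-squared from a Kruskal-Wallis statistic.

    ``eta^2 = (H - k + 1) / (n - k)``, clipped below at 0; ``k`` groups,
    ``n`` total observations.
    """
    if k < 2 or n <= k:
        raise ValueError("need k >= 2 groups and n > k observations")
    return max(0.0, (h - k + 1) / (n - k))


def kruskal_wallis_eta2(groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis test with rank eta-squared.

    ``groups`` is a sequence of k >= 2 nonempty samples. The p-value uses
    the chi-square approximation with ``df = k - 1``. When all pooled
    values are identical the statistic is defined as H = 0 (p = 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    n = sum(g.size for g in groups)
    if n <= k:
        raise ValueError("need more observations than groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    return KruskalResult(
        h=float(h), df=k - 1, p=float(p), eta_squared=eta_squared_from_h(h, k, n)
    )


def pairwise_wilcoxon_bonferroni(groups, exact_max_n: int = 25) -> np.ndarray:
    """Bonferroni-adjusted pairwise two-sample rank-sum tests.

    Two-sided Mann-Whitney tests for each of the k(k-1)/2 group pairs;
    adjusted ``p = min(1, raw p x number of pairs)``. The exact null
    distribution is used when the pooled pair has no ties and both groups
    have at most ``exact_max_n`` observations (where the normal
    approximation errs by more than 0.01); otherwise the normal
    approximation with tie and continuity correction applies. Returns a
    symmetric k x k matrix with NaN on the diagonal.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    n_pairs = k * (k - 1) // 2
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            pooled = np.concatenate([groups[i], groups[j]])
            if np.ptp(pooled) == 0:
                raw = 1.0
            else:
                no_ties = np.unique(pooled).size == pooled.size
                small = max(groups[i].size, groups[j].size) <= exact_max_n
                raw = stats.mannwhitneyu(
                    groups[i],
                    groups[j],
                    alternative="two-sided",
                    method="exact" if no_ties and small else "asymptotic",
                    use_continuity=True,
                ).pvalue
            out[i, j] = out[j, i] = min(1.0, float(raw) * n_pairs)
    return out


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    """Log probability of a table under the fixed-margins null."""
    return log_margin_const - gammaln(table + 1).sum()


def _enumerate_fisher(table: np.ndarray, max_tables: int) -> float | None:
    """Exact p by full enumeration of the fixed-margins table space.

    Returns None when the enumeration exceeds ``max_tables`` candidate
    tables (caller falls back to Monte-Carlo).
    """
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    log_const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    log_p_obs = _log_table_prob(table, log_const)
    r = len(rows)
    count = 0
    total_p = 0.0

    def recurse(row: int, col_rem: np.ndarray, log_acc: float) -> bool:
        """Fill rows depth-first; returns False when the cap is exceeded."""
        nonlocal count, total_p
        if row == r - 1:
            count += 1
            if count > max_tables:
                return False
            log_p = log_acc - gammaln(col_rem + 1).sum()
            if log_p <= log_p_obs + 1e-7:
                total_p += np.exp(log_p)
            return True
        target = rows[row]
        c = len(col_rem)
        cells = np.zeros(c, dtype=int)

        def fill(col: int, remaining: int, log_row: float) -> bool:
            if col == c - 1:
                if remaining > col_rem[c - 1]:
                    return True
                cells[c - 1] = remaining
                return recurse(
                    row + 1,
                    col_rem - cells,
                    log_acc + log_row - gammaln(remaining + 1),
                )
            hi = min(col_rem[col], remaining)
            for v in range(hi + 1):
                cells[col] = v
                if not fill(col + 1, remaining - v, log_row - gammaln(v + 1)):
                    return False
            cells[col] = 0
            return True

        return fill(0, int(target), 0.0)

    # the margin constant is folded into log_acc once, at the root call
    ok = recurse(0, cols.copy(), log_const)
    if not ok:
        return None
    return min(1.0, total_p)


def fisher_exact_rxc(
    table,
    max_tables: int = 1_000_000,
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> FisherResult:
    """Fisher exact test for an r x c contingency table, with chi-square.

    The exact p-value sums the probabilities (under the fixed-margins
    multivariate hypergeometric null) of all tables no more probable than
    the observed one; when the table space exceeds ``max_tables`` candidate
    tables, a Monte-Carlo estimate over ``n_mc`` Patefield draws is used
    (``p = (1 + #{prob <= prob_obs}) / (n_mc + 1)``). The Pearson
    chi-square statistic with ``df = (r-1)(c-1)`` is reported alongside.
    """
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.all(np.asarray(table, float) == np.round(table)):
            raise ValueError("contingency counts must be integers")
        table = table.astype(int)
    if (table < 0).any():
        raise ValueError("contingency counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    # drop all-zero margins: they carry no information
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        # a single nonzero row/column admits exactly one table: no association
        return FisherResult(chi2=0.0, df=0, fisher_p=1.0, method="enumeration")
    chi2, _, df, _ = stats.chi2_contingency(table, correction=False)
    p = _enumerate_fisher(table, max_tables)
    if p is not None:
        return FisherResult(float(chi2), int(df), float(p), "enumeration")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    log_const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(table.sum() + 1)
    log_p_obs = _log_table_prob(table, log_const)
    rng = np.random.default_rng(seed)
    samples = stats.random_table(rows, cols).rvs(n_mc, random_state=rng)
    log_ps = log_const - gammaln(samples + 1).sum(axis=(1, 2))
    hits = int((log_ps <= log_p_obs + 1e-7).sum())
    return FisherResult(float(chi2), int(df), (1 + hits) / (n_mc + 1), "monte_carlo")
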