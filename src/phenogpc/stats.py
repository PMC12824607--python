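"""Statistical engines: exact contingency tests, MTC, rank/means tests, log-rank.

The exact tests use the conventional "Fisher" two-sided definition: the
two-sided p-value sums the probabilities of all tables with the observed
margins whose point probability does not exceed the observed table's point
probability (with a relative tolerance of 1e-7 for ties).  The r x 2 test is
the Freeman-Halton generalization, computed by exhaustive enumeration over
the margin-consistent tables.  All functions are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_TIE_TOL = 1.0 + 1e-7

MTC_METHODS = (
    "bonferroni",
    "sidak",
    "holm",
    "holm-sidak",
    "hommel",
    "hochberg",
    "simes-hochberg",
    "fdr_bh",
    "fdr_by",
    "fdr_tsbh",
    "fdr_tsbky",
)

# statsmodels spells a few of these differently
_MTC_ALIASES = {"hochberg": "simes-hochberg"}


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test outcome with omission accounting."""

    statistic: float | None
    p_raw: float
    p_adjusted: float | None = None
    n_used: int = 0
    n_omitted: int = 0


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an r x 2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return arr


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``greater``/``less`` refer to the count in cell (0, 0) under the
    hypergeometric null with fixed margins.
    """
    arr = _validate_table(table)
    if arr.shape[0] != 2:
        raise ValueError("fisher_exact_2x2 requires exactly 2 rows")
    if arr.sum() < 1:
        raise ValueError("table must contain at least one observation")
    a = int(arr[0, 0])
    r1, r2 = int(arr[0].sum()), int(arr[1].sum())
    c1 = int(arr[:, 0].sum())
    n = r1 + r2
    # support of the (0,0) cell given the margins
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    if alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    elif alternative == "two-sided":
        p = pmf[pmf <= p_obs * _TIE_TOL].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def _log_multivariate_hypergeom(arr: np.ndarray, lgamma_cache=math.lgamma) -> float:
    """Log-probability of an r x 2 table under fixed margins."""
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = arr.sum()
    lg = lgamma_cache
    num = sum(lg(r + 1) for r in rows) + sum(lg(c + 1) for c in cols)
    den = lg(n + 1) + sum(lg(x + 1) for x in arr.ravel())
    return num - den


def exact_rx2(table) -> float:
    """Freeman-Halton exact test for an r x 2 table (r in {2, 3}).

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities not exceeding the observed
    table's probability.  Rows of zeros are dropped first, so a 3x2 table
    with an empty row reduces exactly to the 2x2 test.
    """
    arr = _validate_table(table)
    arr = arr[arr.sum(axis=1) > 0]
    if arr.shape[0] <= 1:
        return 1.0  # a single (or no) non-empty row admits only one table
    if arr.shape[0] == 2:
        return fisher_exact_2x2(arr, alternative="two-sided")
    if arr.shape[0] != 3:
        raise ValueError("exact_rx2 supports at most 3 non-empty rows")
    rows = arr.sum(axis=1)
    c1 = int(arr[:, 0].sum())
    log_p_obs = _log_multivariate_hypergeom(arr)
    total = 0.0
    # enumerate first-column entries (a1, a2, a3) with a1+a2+a3 = c1
    for a1 in range(max(0, c1 - rows[1] - rows[2]), min(rows[0], c1) + 1):
        rem = c1 - a1
        for a2 in range(max(0, rem - rows[2]), min(rows[1], rem) + 1):
            a3 = rem - a2
            cand = np.array(
                [[a1, rows[0] - a1], [a2, rows[1] - a2], [a3, rows[2] - a3]],
                dtype=np.int64,
            )
            log_p = _log_multivariate_hypergeom(cand)
            if math.exp(log_p) <= math.exp(log_p_obs) * _TIE_TOL:
                total += math.exp(log_p)
    return float(min(total, 1.0))


def adjust_pvalues(pvals: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Adjust p-values with one of the 11 classical MTC procedures.

    Delegates to :func:`statsmodels.stats.multitest.multipletests`; output is
    order-preserving with the input and clipped to [0, 1].
    """
    if method not in MTC_METHODS:
        raise ValueError(f"unknown MTC method {method!r}; choose from {MTC_METHODS}")
    pvals = list(pvals)
    if not pvals:
        return []
    if any(p < 0 or p > 1 or not math.isfinite(p) for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(
        pvals, alpha=0.05, method=_MTC_ALIASES.get(method, method)
    )
    return [float(min(p, 1.0)) for p in adjusted]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    ``auto`` uses the exact permutation distribution when the combined sample
    size is at most 12 and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        no_ties = len(set(x + y)) == len(x) + len(y)
        mode = "exact" if (len(x) + len(y) <= 12 and no_ties) else "normal"
    if mode == "exact":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Unpaired two-sided t test (pooled variance by default, Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must contain at least 2 values")
    if x.std() == 0 and y.std() == 0:
        # degenerate: both samples constant
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def log_rank(records: Sequence[tuple[float, bool, str]]) -> tuple[float, float]:
    """Two-class log-rank test on (time, event, class-label) records.

    At each distinct event time the observed events in the first class are
    compared with the hypergeometric expectation given the risk sets; the
    statistic (O - E)^2 / V is referred to chi-square with 1 df.  Tied event
    times are handled by the simultaneous-event convention, and events at a
    time are counted before censorings at the same time leave the risk set.
    """
    if not records:
        raise ValueError("no survival records")
    labels = sorted({lab for _, _, lab in records})
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 classes, got {labels}")
    times = np.array([t for t, _, _ in records], dtype=float)
    events = np.array([bool(e) for _, e, _ in records])
    group0 = np.array([lab == labels[0] for _, _, lab in records])
    if not events.any():
        raise ValueError("no events observed in any class")
    if group0.all() or not group0.any():
        raise ValueError("one class has no records")

    observed = 0.0
    expected = 0.0
    variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & group0).sum()
        d = (events & (times == t)).sum()
        d0 = (events & (times == t) & group0).sum()
        observed += d0
        expected += d * n0 / n
        if n > 1:
            variance += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    return float(chi2), float(sps.chi2.sf(chi2, df=1))
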