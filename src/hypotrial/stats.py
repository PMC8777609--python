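"""Nonparametric trial statistics, implemented from first principles.

The two-arm comparisons used throughout the package are rank-based:

* Mann-Whitney U with an exact permutation null (dynamic-programming count of
  the rank-sum distribution) for small tie-free samples, and a tie-corrected,
  continuity-corrected normal approximation otherwise;
* the Hodges-Lehmann estimate of a location difference — the median of all
  pairwise between-group differences — with a distribution-free confidence
  interval read off the order statistics of those differences at ranks given
  by the Mann-Whitney null;
* Spearman rank correlation (midranks, t-approximation for the p-value);
* Pearson chi-square for contingency tables;
* a Kolmogorov-Smirnov normality check with estimated mean/SD
  (Lilliefors-style), whose p-value comes from Monte-Carlo simulation of the
  null because the classical KS tables do not apply once parameters are
  estimated.

scipy is used only for distribution functions (normal, t, chi-square);
the statistics themselves are authored here so every step is auditable.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

from .series import ARMS, TrialDataset


class InsufficientDataError(ValueError):
    """A sample is empty or too small for the requested statistic."""


class DegenerateInputError(ValueError):
    """Constant sample, zero table margin, or similar degenerate input."""


# ---------------------------------------------------------------------------
# small shared helpers
# ---------------------------------------------------------------------------

def midranks(x: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean rank of the tied block."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def iqr_width(x: Sequence[float]) -> float:
    """Q3 - Q1 with linear (type-7) quartile interpolation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


@lru_cache(maxsize=128)
def _u_null_pmf(m: int, n: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic for sample sizes m, n.

    Classic recursion on the number of rank arrangements: f(u; m, n) counts
    subsets of {1..m+n} of size m whose U equals u.
    """
    # dp[j, u] = number of ways choosing j of the first i elements with U = u
    maxu = m * n
    dp = np.zeros((m + 1, maxu + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, m + n + 1):
        jmax = min(i, m)
        for j in range(jmax, 0, -1):
            # element i assigned to x contributes (i - j) inversions vs y
            shift = i - j
            if shift == 0:
                dp[j, :] += dp[j - 1, :]
            else:
                dp[j, shift:] += dp[j - 1, :maxu + 1 - shift]
    pmf = dp[m]
    pmf /= pmf.sum()
    return pmf


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_limit: int = 400,
) -> Tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``(U, p)`` where U counts pairs (x_i, y_j) with x_i > y_j (ties
    count 1/2).  ``mode='exact'`` enumerates the null rank distribution
    (valid without ties); ``'normal_approx'`` uses the tie-corrected normal
    approximation with continuity correction; ``'auto'`` picks exact when
    ``len(x)*len(y) <= exact_limit`` and the pooled data are tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    has_ties = np.unique(pooled).size < pooled.size
    u = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    if mode == "auto":
        mode = "exact" if (m * n <= exact_limit and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            mode = "normal_approx"  # exact enumeration assumes distinct values
        else:
            pmf = _u_null_pmf(m, n)
            k = int(round(min(u, m * n - u)))
            p = min(1.0, 2.0 * float(pmf[: k + 1].sum()))
            return u, p
    # tie-corrected normal approximation with continuity correction
    N = m + n
    tie_term = 0.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (N * (N - 1))) if N > 1 else 0.0
    sigma2 = m * n / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        # all pooled values identical: the test carries no evidence
        return u, 1.0
    z = (abs(u - m * n / 2.0) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = float(2.0 * _norm.sf(z))
    return u, min(1.0, p)


def hodges_lehmann(
    x: Sequence[float],
    y: Sequence[float],
    conf: float = 0.95,
    exact_limit: int = 2500,
) -> Tuple[float, float, float]:
    """Hodges-Lehmann shift estimate of x - y with a distribution-free CI.

    The estimate is the median of all ``len(x)*len(y)`` pairwise differences
    x_i - y_j.  The CI endpoints are the order statistics of the sorted
    differences at the critical ranks of the Mann-Whitney null distribution
    (exact when ``len(x)*len(y) <= exact_limit``, otherwise the normal
    approximation of the rank); ranks at ties are resolved conservatively so
    the achieved level is at least the nominal one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    est = float(np.median(diffs))
    mn = m * n
    alpha = 1.0 - conf
    if mn <= exact_limit:
        cdf = np.cumsum(_u_null_pmf(m, n))
        # largest u with P(U <= u) <= alpha/2; -1 when even u=0 exceeds it
        ks = np.nonzero(cdf <= alpha / 2.0 + 1e-12)[0]
        k = int(ks[-1]) if ks.size else -1
    else:
        k = int(np.floor(mn / 2.0 - _norm.ppf(1 - alpha / 2.0)
                         * np.sqrt(mn * (m + n + 1) / 12.0)))
        k = max(k, -1)
    if k < 0:
        lo, hi = diffs[0], diffs[-1]
    else:
        lo, hi = diffs[k], diffs[mn - k - 1]
    return est, float(lo), float(hi)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its t-approximation p-value."""

    rho: float
    p_value: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman correlation: Pearson correlation of midranks.

    The p-value uses the usual t approximation with n-2 degrees of freedom;
    perfect correlations map to p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rx = midranks(x)
    ry = midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * _t_dist.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(1.0, p), n=n)


def chi_square(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson chi-square for an R x C contingency table, no continuity
    correction; df = (R-1)(C-1)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateInputError("table must be at least 2x2")
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise DegenerateInputError("counts must be finite and non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateInputError("zero row/column margin")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(_chi2_dist.sf(stat, df=df))


def ks_normality(
    x: Sequence[float],
    reps: int = 2000,
    seed: int = 0,
) -> Tuple[float, float]:
    """KS test against a normal with *estimated* mean/SD (Lilliefors-style).

    The statistic is sup |ECDF - Phi((x - mean)/sd)|.  Because the reference
    normal is fitted to the data, the p-value is obtained by Monte-Carlo:
    ``reps`` standard-normal samples of the same size are subjected to the
    same procedure and the p-value is the (add-one) fraction with a statistic
    at least as large.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.unique(x).size == 1:
        raise DegenerateInputError("constant sample")
    d = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((reps, n))
    sims.sort(axis=1)
    mu = sims.mean(axis=1, keepdims=True)
    sd = sims.std(axis=1, ddof=1, keepdims=True)
    cdf = _norm.cdf((sims - mu) / sd)
    i = np.arange(1, n + 1)
    dplus = (i / n - cdf).max(axis=1)
    dminus = (cdf - (i - 1) / n).max(axis=1)
    dsim = np.maximum(dplus, dminus)
    p = (1.0 + float((dsim >= d - 1e-15).sum())) / (reps + 1.0)
    return float(d), float(min(1.0, p))


def _lilliefors_stat(x: np.ndarray) -> float:
    n = x.size
    xs = np.sort(x)
    mu = xs.mean()
    sd = xs.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant sample")
    cdf = _norm.cdf((xs - mu) / sd)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


# ---------------------------------------------------------------------------
# arm-level comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """One outcome compared between arms, Hodges-Lehmann oriented A - B."""

    outcome_name: str
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    hl_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hl_difference <= self.ci_high):
            raise ValueError("CI must bracket the Hodges-Lehmann estimate")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    outcome_name: str = "outcome",
    conf: float = 0.95,
    alpha: float = 0.05,
    mw_mode: str = "auto",
) -> GroupComparison:
    """Median (IQR) per group, HL difference a - b with CI, Mann-Whitney p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    est, lo, hi = hodges_lehmann(a, b, conf=conf)
    # ties can place the discrete CI endpoint at the estimate's own order
    # statistic; widen to keep the bracket invariant
    lo, hi = min(lo, est), max(hi, est)
    _, p = mann_whitney_u(a, b, mode=mw_mode)
    return GroupComparison(
        outcome_name=outcome_name,
        median_a=float(np.median(a)), iqr_a=iqr_width(a),
        median_b=float(np.median(b)), iqr_b=iqr_width(b),
        hl_difference=est, ci_low=lo, ci_high=hi,
        p_value=p, alpha=alpha,
    )


def compare_arms(
    trial: TrialDataset,
    outcome: str,
    conf: float = 0.95,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare one burden outcome between arms (intervention - control).

    Every patient must carry a burden summary (``patient.summary``); with
    this orientation a beneficial intervention yields a negative difference.
    """
    values = {arm: [] for arm in ARMS}
    for patient in trial:
        if patient.summary is None:
            raise InsufficientDataError(
                f"patient {patient.patient_id!r} has no burden summary"
            )
        values[patient.arm].append(patient.summary.outcome(outcome))
    for arm in ARMS:
        if not values[arm]:
            raise InsufficientDataError(f"arm {arm!r} is empty")
    return compare_groups(
        values["intervention"], values["control"],
        outcome_name=outcome, conf=conf, alpha=alpha,
    )
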