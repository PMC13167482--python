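"""Statistical primitives: binomial proportion intervals, reporting rounding,
and a one-sided Wilcoxon rank-sum test with exact small-sample enumeration.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import beta, norm

__all__ = [
    "wilson_interval",
    "wald_interval",
    "clopper_pearson_interval",
    "binomial_interval",
    "round_half_away",
    "report_percent",
    "rank_sum_less",
]


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Parameters
    ----------
    k : number of successes, ``0 <= k <= n``
    n : number of trials, ``n >= 1``
    conf : two-sided confidence level in (0, 1)

    Returns
    -------
    (low, high) : bounds clipped to [0, 1]; always contains ``k / n``.
    """
    _check_kn(k, n)
    z = norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2.0 * n)
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    # boundary cases are exact in the closed form; snap past float error
    low = 0.0 if k == 0 else (centre - half) / denom
    high = 1.0 if k == n else (centre + half) / denom
    return max(0.0, low), min(1.0, high)


def wald_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Normal-approximation (Wald) interval; provided for comparison only."""
    _check_kn(k, n)
    z = norm.ppf(0.5 + conf / 2.0)
    p = k / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def clopper_pearson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) interval from beta quantiles."""
    _check_kn(k, n)
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


_INTERVAL_METHODS = {
    "wilson": wilson_interval,
    "wald": wald_interval,
    "clopper_pearson": clopper_pearson_interval,
}


def binomial_interval(
    k: int, n: int, conf: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Dispatch to a named binomial interval method (default ``wilson``)."""
    try:
        fn = _INTERVAL_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown interval method {method!r}; choose from {sorted(_INTERVAL_METHODS)}"
        ) from None
    return fn(k, n, conf)


def _check_kn(k: int, n: int) -> None:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")


def round_half_away(x: float, places: int = 1) -> float:
    """Round half away from zero at ``places`` decimal places.

    Python's built-in ``round`` is banker's rounding; reported percentages
    use the conventional half-away rule (81.25 -> 81.3, 12.5 -> 13).
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x}")
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def report_percent(x: float, places: int = 1) -> str:
    """Format a proportion ``x`` as a rounded percentage string.

    >>> report_percent(13 / 16)
    '81.3%'
    >>> report_percent(2 / 16, places=0)
    '13%'
    """
    value = round_half_away(100.0 * x, places)
    return f"{value:.{places}f}%"


def rank_sum_less(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_min: int = 8,
    exact_total: int = 20,
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test of "a stochastically smaller than b".

    Returns ``(p_value, u_statistic)`` where the statistic is the
    Mann-Whitney U of sample a (number of (a, b) pairs with a > b, counting
    ties as 1/2; small values support the "less" alternative).  The exact null distribution is enumerated when
    ``min(n_a, n_b) <= exact_min`` and ``n_a + n_b <= exact_total``;
    otherwise a normal approximation with midrank tie correction and
    continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_less requires both samples to be nonempty")

    u_obs = _u_statistic(a, b)
    na, nb = a.size, b.size
    if min(na, nb) <= exact_min and na + nb <= exact_total:
        p = _exact_p_less(a, b, u_obs)
    else:
        p = _approx_p_less(a, b, u_obs)
    return p, u_obs


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    # U_a via midrank sum: U = R_a - n_a(n_a+1)/2
    pooled = np.concatenate([a, b])
    _, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    csum = np.cumsum(counts)
    midrank = csum - (counts - 1) / 2.0
    ranks = midrank[inv]
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_p_less(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Enumerate every assignment of the pooled multiset to group a."""
    pooled = np.concatenate([a, b])
    na = a.size
    n = pooled.size
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        # small epsilon guards float equality of midrank-derived statistics
        if u <= u_obs + 1e-9:
            count += 1
        total += 1
    return count / total


def _approx_p_less(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mu = na * nb / 2.0
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        # all values identical: no evidence of shift
        return 1.0
    z = (u_obs - mu + 0.5) / math.sqrt(var)
    return float(norm.cdf(z))
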