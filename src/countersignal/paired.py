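"""Exact Wilcoxon signed-rank test for paired release rates.

Small samples (n <= 20 after dropping zero differences) are handled by full
enumeration of the 2^n equiprobable sign assignments, with mid-ranks for tied
absolute differences — the regime these bioassays live in (4-13 males per
treatment), where the normal approximation is unreliable and tied ranks from
simulated data must still yield exact p-values.  Larger samples fall back to
the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass
class WilcoxonResult:
    statistic: float        # W+: sum of ranks of positive differences
    p_value: float
    n: int                  # pairs used (zero differences dropped)
    method: str             # "exact" or "approx"


def _signed_rank_distribution(scaled_ranks: np.ndarray) -> np.ndarray:
    """Probability distribution of W+ (on the doubled-rank integer grid).

    Mid-ranks are half-integers, so ranks are doubled to integers and the
    distribution of their signed sum is built by dynamic programming:
    dist[k] = number of sign assignments with doubled-W+ equal to k.
    """
    total = int(scaled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    return dist / dist.sum()


def wilcoxon_signed_rank(x, y=None, alternative: str = "two_sided",
                         exact_max_n: int = 20) -> WilcoxonResult:
    """Wilcoxon signed-rank test on pairs (x, y) or precomputed differences.

    Differences are y - x (post minus baseline) when two arrays are given,
    or x itself when ``y is None``.  Zero differences are dropped and n
    reduced (Wilcoxon's convention).  The two-sided p-value is
    min(1, 2 * min(one-sided p's)) — the enumeration distribution can be
    asymmetric under ties, so doubling is used rather than summing both tails.
    """
    if alternative not in ALTERNATIVES:
        raise DomainError(f"alternative must be one of {ALTERNATIVES} (got {alternative!r})")
    d = np.asarray(x, dtype=float) if y is None else np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    if d.size == 0:
        raise DegenerateDataError("no pairs supplied")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all differences are zero")

    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        scaled = np.rint(ranks * 2).astype(int)
        dist = _signed_rank_distribution(scaled)
        w_scaled = int(round(w_plus * 2))
        p_greater = float(dist[w_scaled:].sum())
        p_less = float(dist[: w_scaled + 1].sum())
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return WilcoxonResult(statistic=w_plus, p_value=min(p, 1.0), n=n, method="exact")

    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = stats.wilcoxon(d, alternative=alt, correction=True, method="approx")
    return WilcoxonResult(statistic=w_plus, p_value=float(res.pvalue), n=n, method="approx")
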