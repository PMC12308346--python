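"""Baseline-dependence of the fold-change response, corrected for coupling.

Correlating a fold-change y/x with its own denominator x produces a spurious
negative correlation even when y carries no information about x beyond the
coupling ("mathematical coupling").  The test implemented here compares the
observed correlation r(x, y/x) with the null correlation expected from
coupling alone,

    r_null = -sqrt((1 - r_xy) / 2),

the change-score null correlation under equal variances, via Fisher's
z-transform and a z-test.  Correlations are computed on the logarithmic
scale, where the ratio becomes a difference (ln(y/x) = ln y - ln x) and the
null formula is exact for equal log-variances.

Because r_null is estimated from the *same* sample as r_obs and the two
Fisher transforms are positively correlated, the naive standard error
1/sqrt(n-3) overstates the variance of their difference; the delta-method
variance at the uncoupled null is 1/(2(n-3)) (see the methods note), and the
default test uses that.  ``variance_corrected=False`` gives the conservative
uncorrected statistic.  A permutation oracle that breaks the (x, y) pairing
and recomputes the coupled correlation is provided as the assumption-free
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError

NULL_METHODS = ("tu_default", "literal")


@dataclass
class CouplingTestResult:
    n: int
    r_obs: float        # Pearson correlation of (ln x, ln(y/x))
    r_xy: float         # Pearson correlation of (ln x, ln y)
    r_null: float       # expected correlation from coupling alone
    z_stat: float
    p_value: float
    null_method: str
    variance_corrected: bool


@dataclass
class PermutationNullResult:
    n: int
    n_perm: int
    r_obs: float
    null_mean: float
    null_r: np.ndarray
    p_value: float


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = arctanh(r); odd in r."""
    r = float(r)
    if not abs(r) < 1.0:
        raise DomainError(f"|r| must be < 1 (got {r})")
    return math.atanh(r)


def null_correlation(r_xy: float, method: str = "tu_default") -> float:
    """Expected correlation of x with y/x when y is coupled to x only by the ratio.

    ``tu_default``: -sqrt((1 - r_xy)/2), the equal-variance change-score null.
    ``literal``: r_xy - (1 - r_xy)/2, retained for comparison; it fails the
    permutation-oracle check (see the test suite) and is not the default.
    """
    r_xy = float(r_xy)
    if abs(r_xy) > 1.0:
        raise DomainError(f"|r_xy| must be <= 1 (got {r_xy})")
    if method == "tu_default":
        return -math.sqrt((1.0 - r_xy) / 2.0)
    if method == "literal":
        return r_xy - (1.0 - r_xy) / 2.0
    raise DomainError(f"method must be one of {NULL_METHODS} (got {method!r})")


def _log_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    if x.size < 4:
        raise DomainError(f"need n >= 4 pairs (got {x.size})")
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("all rates must be > 0")
    return np.log(x), np.log(y)


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    # relative tolerance: a ratio that is constant up to float rounding
    # (e.g. y exactly proportional to x) must register as zero variance
    for w in (u, v):
        if w.std() <= 1e-10 * (np.abs(w).max() + 1e-300):
            raise DegenerateDataError("zero variance in one of the correlated variables")
    return float(np.clip(np.corrcoef(u, v)[0, 1], -1.0, 1.0))


def coupling_test(x, y, *, null_method: str = "tu_default",
                  variance_corrected: bool = True) -> CouplingTestResult:
    """Test whether the fold-change y/x depends on baseline x beyond coupling.

    z = (arctanh(r_obs) - arctanh(r_null)) / SE with SE = 1/sqrt(2(n-3))
    by default (1/sqrt(n-3) when ``variance_corrected=False``); two-sided p
    from the standard normal.  A negative z indicates that low-baseline males
    respond with larger fold-changes than coupling alone would produce.
    """
    lx, ly = _log_pairs(x, y)
    n = lx.size
    r_obs = _corr(lx, ly - lx)
    r_xy = _corr(lx, ly)
    r_null = null_correlation(r_xy, method=null_method)
    cap = 1.0 - 1e-12
    z_obs = math.atanh(np.clip(r_obs, -cap, cap))
    z_null = math.atanh(np.clip(r_null, -cap, cap))
    scale = math.sqrt(2.0 * (n - 3)) if variance_corrected else math.sqrt(n - 3)
    z = (z_obs - z_null) * scale
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return CouplingTestResult(n=n, r_obs=r_obs, r_xy=r_xy, r_null=r_null,
                              z_stat=z, p_value=min(p, 1.0),
                              null_method=null_method,
                              variance_corrected=variance_corrected)


def naive_coupling_test(x, y) -> tuple[float, float]:
    """z-test of H0: corr(x, y/x) = 0, ignoring coupling (for comparison only)."""
    lx, ly = _log_pairs(x, y)
    r_obs = _corr(lx, ly - lx)
    z = math.atanh(np.clip(r_obs, -1 + 1e-12, 1 - 1e-12)) * math.sqrt(lx.size - 3)
    return z, min(2.0 * float(stats.norm.sf(abs(z))), 1.0)


def permutation_null_oracle(x, y, n_perm: int = 2000, seed: int = 0) -> PermutationNullResult:
    """Empirical null of r(x, y/x) by permuting y against x.

    Breaking the pairing removes any true baseline-dependence while keeping
    the coupling (the permuted y is still divided by x), so the permutation
    distribution of r_obs is the coupling-only null.  p is the add-one
    smoothed fraction of permutations at least as far from the null mean as
    the observed correlation.
    """
    if n_perm < 200:
        raise DomainError(f"n_perm must be >= 200 (got {n_perm})")
    lx, ly = _log_pairs(x, y)
    r_obs = _corr(lx, ly - lx)
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(ly)
        null_r[i] = _corr(lx, perm - lx)
    null_mean = float(null_r.mean())
    extreme = np.abs(null_r - null_mean) >= abs(r_obs - null_mean) - 1e-15
    p = (int(extreme.sum()) + 1) / (n_perm + 1)
    return PermutationNullResult(n=lx.size, n_perm=n_perm, r_obs=r_obs,
                                 null_mean=null_mean, null_r=null_r, p_value=p)
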