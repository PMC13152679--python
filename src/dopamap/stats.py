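"""Small-sample statistics for figure-level comparisons.

Group sizes in slice and retina experiments are tiny (n = 2–7), so the
Mann–Whitney U test is computed *exactly* by enumerating all C(n₁+n₂, n₂)
group assignments whenever the pooled sample is small and tie-free; ties
fall back to a seeded permutation test and large samples to the normal
approximation with continuity correction.  Both one- and two-sided p-values
are always reported, with the method labeled, because published values for
such tiny groups are often one-sided tails of the exact distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_t",
    "p_from_t",
    "mann_whitney",
    "exact_u_sf",
    "linreg",
    "LinregResult",
]


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_one_sided: float
    p_two_sided: float
    method: str


def p_from_t(t: float, df: float) -> float:
    """Two-sided p-value from a Student-t statistic.

    At df = 2 this has the closed form 1 − |t|/√(t² + 2).
    """
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_t(x, y) -> TestResult:
    """Paired t test on differences d = x − y.

    t = mean(d)/(sd(d)/√n) with df = n − 1; all-zero (or constant)
    differences have no dispersion and are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired samples must be equal-length 1-D arrays, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "differences have zero variance; the paired t statistic is undefined"
        )
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_one_sided=float(sps.t.sf(abs(t), df)),
        p_two_sided=p_from_t(t, df),
        method="exact",
    )


def _exact_u_distribution(ranks: np.ndarray, n_y: int) -> dict[float, int]:
    """Counts of U_y over all assignments of ``n_y`` of the pooled ranks to y."""
    base = n_y * (n_y + 1) / 2.0
    dist: dict[float, int] = {}
    for idx in combinations(range(len(ranks)), n_y):
        u = ranks[list(idx)].sum() - base
        dist[u] = dist.get(u, 0) + 1
    return dist


def exact_u_sf(u: float, n_x: int, n_y: int) -> float:
    """Exact one-sided tail P(U ≥ u) of the null Mann–Whitney distribution.

    Computed by full enumeration of all C(n_x+n_y, n_y) rank assignments
    (tie-free null).  By the symmetry of the two groups' U statistics the
    tail is the same whichever group U refers to.
    """
    ranks = np.arange(1, n_x + n_y + 1, dtype=float)
    dist = _exact_u_distribution(ranks, n_y)
    total = comb(n_x + n_y, n_y)
    return sum(c for val, c in dist.items() if val >= u) / total


def mann_whitney(
    x,
    y,
    exact_max_n: int = 12,
    n_perm: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Mann–Whitney U test, exact for small tie-free samples.

    U for each group is computed from midranks.  When n_x + n_y ≤
    ``exact_max_n`` and there are no ties, p-values come from full
    enumeration of group assignments; ties trigger a seeded permutation
    test with ``n_perm`` draws; otherwise the normal approximation with
    continuity correction is used.  The reported statistic is U of the
    first sample; the one-sided p is the tail in the observed direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0)
    mean_u = n_x * n_y / 2.0
    u_hi = max(u_x, n_x * n_y - u_x)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n_x + n_y <= exact_max_n and not has_ties:
        dist = _exact_u_distribution(ranks, n_x)  # distribution of U_x
        total = comb(n_x + n_y, n_x)
        p_one = sum(c for v, c in dist.items() if v >= u_hi) / total
        p_two = min(
            1.0,
            sum(c for v, c in dist.items() if v >= u_hi) / total
            + sum(c for v, c in dist.items() if v <= n_x * n_y - u_hi) / total,
        )
        method = "exact"
    elif has_ties:
        rng = np.random.default_rng(seed)
        base = n_x * (n_x + 1) / 2.0
        obs_dev = abs(u_x - mean_u)
        sign = 1.0 if u_x >= mean_u else -1.0
        # vectorized random group assignments via random-key argsort
        keys = rng.random((n_perm, n_x + n_y))
        idx = np.argsort(keys, axis=1)[:, :n_x]
        u = ranks[idx].sum(axis=1) - base
        p_one = (np.sum(sign * (u - mean_u) >= sign * (u_x - mean_u)) + 1) / (n_perm + 1)
        p_two = (np.sum(np.abs(u - mean_u) >= obs_dev) + 1) / (n_perm + 1)
        method = "permutation"
    else:
        sigma = np.sqrt(n_x * n_y * (n_x + n_y + 1) / 12.0)
        z = (u_hi - mean_u - 0.5) / sigma
        p_one = float(sps.norm.sf(z))
        p_two = min(1.0, 2.0 * p_one)
        method = "normal_approx"
    return TestResult(
        statistic=u_x,
        df=None,
        p_one_sided=float(min(1.0, p_one)),
        p_two_sided=float(min(1.0, p_two)),
        method=method,
    )


@dataclass
class LinregResult:
    slope: float
    intercept: float
    r_squared: float


def linreg(x, y) -> LinregResult:
    """Ordinary least-squares regression with R² = 1 − SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("samples must be equal-length 1-D arrays, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression slope undefined")
    res = sps.linregress(x, y)
    return LinregResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
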